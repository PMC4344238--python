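"""Self-contained synthetic benchmark worlds with known ground truth.

A scenario simulates the statistical structure the inference workflow
assumes: a target genome plus related genomes sharing orthologous genes in
a largely conserved order; per-TF binding motifs planted (with per-genome
mutation and ortholog loss) in the upstream intergenic regions of regulon
members in genomes where the TF is present; operon chains downstream of
some members; and a condition-dependent expression compendium in which each
regulon follows its TF's latent activity on an active condition subset.
Post-transcriptionally regulated TFs have expression profiles unrelated to
their targets, which is the regime where non-expression evidence must carry
the prediction.

All genes are laid on the forward strand so that every gene's upstream
intergenic region is exactly the gap to its left neighbour; motif instances
are still embedded on either strand at random.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from trninfer import genome_io
from trninfer.evaluation import GoldStandard, write_gold
from trninfer.expression import write_expression
from trninfer.genome_io import GeneRecord, OrthologGroup
from trninfer.motif_engine import DNA, PSSM, BackgroundModel, write_meme_minimal
from trninfer.tf_linking import ReferenceMotifLibrary

_FAMILIES = [
    "Crp", "LacI", "GntR", "LysR", "TetR", "ArsR",
    "MarR", "Fur", "IclR", "MerR", "BadM", "OmpR",
]
_DECOY_FAMILIES = ["AraC", "DeoR", "AsnC", "ColdShock", "PadR", "Xre"]


@dataclass
class SyntheticScenario:
    """Parameters of a synthetic world; defaults describe the standard
    benchmark conditions (8 genomes, 300 ortholog groups, 12 TFs, 120
    conditions)."""

    n_genomes: int = 8
    n_ortholog_groups: int = 300
    n_tfs: int = 12
    regulon_size_min: int = 5
    regulon_size_max: int = 15
    motif_width_min: int = 10
    motif_width_max: int = 18
    igr_len_min: int = 60
    igr_len_max: int = 300
    motif_mutation_rate: float = 0.05  # per base per genome
    ortholog_loss_prob: float = 0.1
    n_conditions: int = 120
    expression_noise_sd: float = 0.4
    frac_post_transcriptional: float = 0.33
    frac_active_conditions: float = 0.4
    n_operon_chains: int = 8
    operon_gap: int = 20  # bp; below the 40 bp IGR threshold
    gene_length: int = 300
    tf_adjacent_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 4:
            raise ValueError("need at least 4 genomes for the >=4-IGR filter to be passable")
        for p in (
            self.motif_mutation_rate,
            self.ortholog_loss_prob,
            self.frac_post_transcriptional,
            self.frac_active_conditions,
            self.tf_adjacent_prob,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


PRESETS: dict[str, dict] = {
    # low mutation / low noise, fully transcriptional TFs
    "easy": {"motif_mutation_rate": 0.02, "expression_noise_sd": 0.2, "frac_post_transcriptional": 0.0},
    # elevated divergence and noise
    "hard": {"motif_mutation_rate": 0.08, "expression_noise_sd": 0.6, "frac_post_transcriptional": 0.33},
    # every TF post-transcriptionally regulated: correlation carries no signal
    "post_transcriptional": {
        "motif_mutation_rate": 0.02,
        "expression_noise_sd": 0.2,
        "frac_post_transcriptional": 1.0,
        "n_ortholog_groups": 150,
        "n_tfs": 10,
    },
}


def scenario_from_preset(name: str, seed: int = 0, **overrides) -> SyntheticScenario:
    params = dict(PRESETS[name])
    params.update(overrides)
    return SyntheticScenario(seed=seed, **params)


@dataclass
class GroundTruth:
    planted_pssms: dict[str, PSSM]
    regulons: dict[str, set[str]]  # TF -> direct members (target-genome gene ids)
    operon_chains: list[list[str]]  # transcription-ordered target gene ids
    active_conditions: dict[str, set[str]]
    tf_modes: dict[str, str]  # transcriptional | post_transcriptional
    gold: GoldStandard
    tf_families: dict[str, str] = field(default_factory=dict)


@dataclass
class SyntheticWorld:
    scenario: SyntheticScenario
    genome_ids: list[str]
    target_genome: str
    replicon_seqs: dict[str, dict[str, str]]  # genome -> replicon -> sequence
    annotations: dict[str, list[GeneRecord]]  # genome -> records
    ortholog_groups: list[OrthologGroup]
    expression: pd.DataFrame  # target-genome genes x conditions
    tf_table: pd.DataFrame  # tf_id, dbd_family, replicon, gene_index
    library: ReferenceMotifLibrary
    truth: GroundTruth


def _random_background(rng: np.random.Generator, order: int = 3) -> BackgroundModel:
    cond = []
    for k in range(order + 1):
        rows = rng.dirichlet(np.full(4, 12.0), size=4**k)
        cond.append(rows)
    return BackgroundModel(order=order, cond=cond)


def _planted_pssm(rng: np.random.Generator, width: int, motif_id: str) -> PSSM:
    cols = np.empty((4, width))
    for j in range(width):
        if rng.random() < 0.8:
            dom = rng.integers(4)
            col = np.full(4, 0.03)
            col[dom] = 0.91
        else:
            a, b = rng.choice(4, size=2, replace=False)
            col = np.full(4, 0.05)
            col[a] = col[b] = 0.45
        cols[:, j] = col
    return PSSM(motif_id=motif_id, counts=cols * 1000, n_sites=1000, pseudocount=0.0, source="reference")


def _sample_site(pssm: PSSM, rng: np.random.Generator, mutation_rate: float) -> str:
    """A binding-site instance: sampled from the PSSM then point-mutated at
    ``mutation_rate`` per base.  A rate of exactly 0 yields the consensus
    (the no-divergence limit)."""
    if mutation_rate == 0:
        return pssm.consensus
    w = pssm.width
    bases = np.array([rng.choice(4, p=pssm.freqs[:, j]) for j in range(w)])
    mut = rng.random(w) < mutation_rate
    for j in np.nonzero(mut)[0]:
        choices = [b for b in range(4) if b != bases[j]]
        bases[j] = rng.choice(choices)
    return "".join(DNA[b] for b in bases)


def _revcomp(seq: str) -> str:
    return genome_io.revcomp(seq)


def simulate_genomes(scenario: SyntheticScenario) -> SyntheticWorld:
    """Build genomes, annotations, ortholog groups, planted motifs,
    expression data, the reference motif library and the gold standard."""
    rng = np.random.default_rng(scenario.seed)
    sc = scenario
    genome_ids = [f"genome{i:02d}" for i in range(sc.n_genomes)]
    target = genome_ids[0]

    n_groups = sc.n_ortholog_groups
    group_ids = [f"G{i:04d}" for i in range(n_groups)]
    tf_groups = group_ids[: sc.n_tfs]
    regular_groups = group_ids[sc.n_tfs :]

    # regulons over non-TF groups, disjoint
    pool = list(regular_groups)
    rng.shuffle(pool)
    regulon_groups: dict[str, list[str]] = {}
    pos = 0
    for t, tf_grp in enumerate(tf_groups):
        size = int(rng.integers(sc.regulon_size_min, sc.regulon_size_max + 1))
        regulon_groups[tf_grp] = pool[pos : pos + size]
        pos += size
    if pos > len(pool):
        raise ValueError("too many/large regulons for the number of ortholog groups")

    # operon chains: extra genes appended after randomly chosen regulon members
    all_members = [g for mem in regulon_groups.values() for g in mem]
    chain_heads = list(rng.choice(all_members, size=min(sc.n_operon_chains, len(all_members)), replace=False))
    operon_group_ids: list[str] = []
    chains: dict[str, list[str]] = {}
    for c, head in enumerate(chain_heads):
        n_extra = int(rng.integers(1, 3))
        extras = [f"OP{c:02d}_{k}" for k in range(n_extra)]
        chains[head] = extras
        operon_group_ids.extend(extras)

    # block layout: regular/operon blocks, then TF blocks inserted (adjacent with prob 0.5)
    blocks: list[list[str]] = []
    for g in regular_groups:
        if g in chains:
            blocks.append([g] + chains[g])
        else:
            blocks.append([g])
    rng.shuffle(blocks)
    for tf_grp in tf_groups:
        members = regulon_groups[tf_grp]
        if members and rng.random() < sc.tf_adjacent_prob:
            anchor = members[int(rng.integers(len(members)))]
            idx = next(i for i, b in enumerate(blocks) if b[0] == anchor)
            blocks.insert(idx + int(rng.integers(2)), [tf_grp])
        else:
            blocks.insert(int(rng.integers(len(blocks) + 1)), [tf_grp])

    # TF presence across genomes (target always present)
    presence: dict[str, dict[str, bool]] = {
        tf_grp: {g: (g == target or rng.random() >= sc.ortholog_loss_prob) for g in genome_ids}
        for tf_grp in tf_groups
    }

    # per-genome block loss (target genome keeps everything); TF blocks follow presence
    block_present: dict[str, dict[int, bool]] = {}
    for g in genome_ids:
        keep: dict[int, bool] = {}
        for i, b in enumerate(blocks):
            if b[0] in tf_groups:
                keep[i] = presence[b[0]][g]
            else:
                keep[i] = g == target or rng.random() >= sc.ortholog_loss_prob
        block_present[g] = keep

    # planted motifs
    planted: dict[str, PSSM] = {}
    for tf_grp in tf_groups:
        w = int(rng.integers(sc.motif_width_min, sc.motif_width_max + 1))
        planted[tf_grp] = _planted_pssm(rng, w, motif_id=f"planted_{tf_grp}")

    bg = _random_background(rng)
    member_of = {m: tf for tf, mem in regulon_groups.items() for m in mem}

    replicon_seqs: dict[str, dict[str, str]] = {}
    annotations: dict[str, list[GeneRecord]] = {}
    gene_names: dict[tuple[str, str], str] = {}  # (genome, group) -> gene id
    for g in genome_ids:
        order = [i for i in range(len(blocks)) if block_present[g][i]]
        if g != target and len(order) > 1:
            # small local shuffles of block order
            for _ in range(max(1, len(order) // 20)):
                j = int(rng.integers(len(order) - 1))
                order[j], order[j + 1] = order[j + 1], order[j]
        seq_parts: list[str] = []
        rows = []
        posn = 0
        replicon = f"{g}_chr"
        for bi in order:
            for k, grp in enumerate(blocks[bi]):
                gap = sc.operon_gap if k > 0 else int(rng.integers(sc.igr_len_min + 1, sc.igr_len_max + 1))
                igr = bg.sample(gap, rng)
                tf_owner = member_of.get(grp)
                if tf_owner is not None and k == 0 and presence[tf_owner][g]:
                    site = _sample_site(planted[tf_owner], rng, sc.motif_mutation_rate)
                    if rng.random() < 0.5:
                        site = _revcomp(site)
                    off = int(rng.integers(0, gap - len(site) + 1))
                    igr = igr[:off] + site + igr[off + len(site) :]
                body = "".join(rng.choice(list(DNA), sc.gene_length))
                seq_parts.append(igr)
                start = posn + gap + 1
                end = start + sc.gene_length - 1
                seq_parts.append(body)
                posn = end
                gid = f"{g}_{grp}"
                gene_names[(g, grp)] = gid
                rows.append((gid, replicon, start, end, "+"))
        replicon_seqs[g] = {replicon: "".join(seq_parts)}
        annotations[g] = genome_io.load_annotations(
            pd.DataFrame(rows, columns=["gene_id", "replicon", "start", "end", "strand"]), g
        )

    # ortholog groups (operon genes get their own groups too)
    groups: list[OrthologGroup] = []
    for grp in group_ids + operon_group_ids:
        members: dict[str, list[str]] = {}
        for g in genome_ids:
            gid = gene_names.get((g, grp))
            if gid is not None:
                members[g] = [gid]
        groups.append(OrthologGroup(group_id=grp, members=members))

    # ground truth in target-genome gene ids
    tfs = [gene_names[(target, tf_grp)] for tf_grp in tf_groups]
    tf_of_group = dict(zip(tf_groups, tfs))
    regulons: dict[str, set[str]] = {
        tf_of_group[tg]: {gene_names[(target, m)] for m in mem} for tg, mem in regulon_groups.items()
    }
    operon_chains = [
        [gene_names[(target, head)]] + [gene_names[(target, e)] for e in extras]
        for head, extras in chains.items()
    ]
    gold_edges: set[tuple[str, str]] = set()
    for tf, members in regulons.items():
        for m in members:
            gold_edges.add((tf, m))
        for chain in operon_chains:
            if chain[0] in members:
                for extra in chain[1:]:
                    gold_edges.add((tf, extra))
    modes = {
        tf: ("post_transcriptional" if rng.random() < sc.frac_post_transcriptional else "transcriptional")
        for tf in tfs
    }

    # expression
    conditions = [f"cond{j:03d}" for j in range(sc.n_conditions)]
    target_genes = [r.gene_id for r in annotations[target]]
    expr = pd.DataFrame(
        rng.normal(size=(len(target_genes), sc.n_conditions)), index=target_genes, columns=conditions
    )
    active: dict[str, set[str]] = {}
    n_active = max(2, int(round(sc.frac_active_conditions * sc.n_conditions)))
    for tf_grp, tf in tf_of_group.items():
        activity = rng.normal(size=sc.n_conditions)
        act_idx = rng.choice(sc.n_conditions, size=n_active, replace=False)
        active[tf] = {conditions[i] for i in act_idx}
        for m in sorted(regulons[tf]):
            sign = 1.0 if rng.random() < 0.7 else -1.0
            row = expr.loc[m].to_numpy()
            row[act_idx] = sign * activity[act_idx] + sc.expression_noise_sd * rng.normal(size=n_active)
            expr.loc[m] = row
        if modes[tf] == "transcriptional":
            expr.loc[tf] = activity + sc.expression_noise_sd * rng.normal(size=sc.n_conditions)
        # post-transcriptional TFs keep their independent noise row
    for chain in operon_chains:
        head = chain[0]
        for extra in chain[1:]:
            expr.loc[extra] = expr.loc[head].to_numpy() + 0.1 * rng.normal(size=sc.n_conditions)

    # TF table and reference motif library
    fam_cycle = [_FAMILIES[i % len(_FAMILIES)] for i in range(sc.n_tfs)]
    tf_families = dict(zip(tfs, fam_cycle))
    gene_index = {r.gene_id: (r.replicon_id, r.gene_index) for r in annotations[target]}
    tf_rows = [
        (tf, tf_families[tf], gene_index[tf][0], gene_index[tf][1]) for tf in tfs
    ]
    tf_table = pd.DataFrame(tf_rows, columns=["tf_id", "dbd_family", "replicon", "gene_index"])

    lib_entries = []
    for tf_grp, tf in tf_of_group.items():
        sites = [_sample_site(planted[tf_grp], rng, 0.03) for _ in range(20)]
        from trninfer.motif_engine import build_pssm

        ref = build_pssm(sites, motif_id=f"ref_{tf_families[tf]}", source="reference")
        lib_entries.append((ref, f"ref_{tf}", tf_families[tf]))
    for d, fam in enumerate(_DECOY_FAMILIES):
        decoy = _planted_pssm(rng, int(rng.integers(sc.motif_width_min, sc.motif_width_max + 1)), f"decoy_{fam}")
        lib_entries.append((decoy, f"decoy_tf_{d}", fam))

    truth = GroundTruth(
        planted_pssms={tf_of_group[tg]: p for tg, p in planted.items()},
        regulons=regulons,
        operon_chains=operon_chains,
        active_conditions=active,
        tf_modes=modes,
        gold=GoldStandard(interactions=gold_edges, tfs_with_data=set(tfs)),
        tf_families=tf_families,
    )
    return SyntheticWorld(
        scenario=sc,
        genome_ids=genome_ids,
        target_genome=target,
        replicon_seqs=replicon_seqs,
        annotations=annotations,
        ortholog_groups=groups,
        expression=expr,
        tf_table=tf_table,
        library=ReferenceMotifLibrary(entries=lib_entries),
        truth=truth,
    )


def simulate_expression(scenario: SyntheticScenario, world: SyntheticWorld) -> pd.DataFrame:
    """The expression matrix of a simulated world (generated jointly with
    the genomes; exposed separately for API symmetry)."""
    return world.expression


def emit_gold(world: SyntheticWorld, outdir: str | Path) -> None:
    """Write the ground-truth files: gold interactions, assayed TFs, true
    module condition sets, and planted PSSMs (MEME minimal)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gold(world.truth.gold, outdir / "gold_interactions.tsv", outdir / "assayed_tfs.tsv")
    rows = [
        (tf, ",".join(sorted(conds)))
        for tf, conds in sorted(world.truth.active_conditions.items())
    ]
    pd.DataFrame(rows, columns=["tf", "active_conditions"]).to_csv(
        outdir / "true_modules.tsv", sep="\t", index=False
    )
    write_meme_minimal(list(world.truth.planted_pssms.values()), outdir / "planted_motifs.meme")


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Write every input format the pipeline reads, plus gold files and a
    manifest recording the scenario parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g in world.genome_ids:
        genome_io.write_fasta(world.replicon_seqs[g], outdir / f"{g}.fasta")
        pd.DataFrame(
            [(r.gene_id, r.replicon_id, r.start, r.end, r.strand) for r in world.annotations[g]],
            columns=["gene_id", "replicon", "start", "end", "strand"],
        ).to_csv(outdir / f"{g}_genes.tsv", sep="\t", index=False)
    genome_io.write_ortholog_groups(world.ortholog_groups, outdir / "ortholog_groups.tsv")
    write_expression(world.expression, outdir / "expression.tsv")
    world.tf_table.to_csv(outdir / "tf_table.tsv", sep="\t", index=False)
    write_meme_minimal([e[0] for e in world.library.entries], outdir / "reference_motifs.meme")
    pd.DataFrame(
        [(p.motif_id, name, fam) for p, name, fam in world.library.entries],
        columns=["motif_id", "tf_name", "dbd_family"],
    ).to_csv(outdir / "reference_motif_labels.tsv", sep="\t", index=False)
    emit_gold(world, outdir)
    manifest = dataclasses.asdict(world.scenario)
    manifest["genome_ids"] = world.genome_ids
    manifest["target_genome"] = world.target_genome
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
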