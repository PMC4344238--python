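"""End-to-end TRN inference: footprinting groups -> motif discovery ->
motif clustering -> expression refinement -> TF linking -> core network ->
expression consensus -> merged network.
"""

from __future__ import annotations

import logging
import zlib
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trninfer import consensus as cns
from trninfer import expression as expr_mod
from trninfer import genome_io, motif_engine, network, tf_linking
from trninfer.evaluation import GoldStandard, precision, recall
from trninfer.expression import Bicluster
from trninfer.motif_engine import PSSM, MotifFamilyCluster
from trninfer.synthetic import SyntheticWorld
from trninfer.tf_linking import TFClusterScore, TFRecord

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    min_igr_len: int = 40
    min_group_seqs: int = 4
    bg_order: int = 3
    discovery_widths: tuple[int, ...] = (10, 16)
    nmotifs: int = 3
    evalue_max: float = 0.01
    calib_profiles: int = 25
    calib_null_per_profile: int = 3
    hit_p_max: float = 1e-4
    pair_q_max: float = 0.01
    min_overlap: float = 0.33
    hit_bin: int = 5
    compare_shuffles: int = 1000
    min_module: int = 3
    min_conditions: int = 30
    bicluster_p_max: float = 0.001
    max_modules_per_cluster: int = 3
    operon_r_min: float = 0.8
    operon_max_gap: int = 50
    n_null: int = 1000
    n_perm_consensus: int = 10_000
    target_precision: float = 0.95
    default_cutoff: float = 1.3  # consensus score cutoff when no gold is available
    seed: int = 0


@dataclass
class PipelineResult:
    biclusters: list[Bicluster]
    motif_clusters: list[MotifFamilyCluster]
    cluster_pssms: dict[str, PSSM]
    rankings: dict[str, list[TFClusterScore]]
    scores: dict[str, list[TFClusterScore]]
    core: network.RegulatoryNetwork
    merged: network.RegulatoryNetwork
    consensus_edges: list
    consensus_cutoff: float | None
    expression_std: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _derive_seed(base: int, tag: str) -> int:
    # zlib.crc32 is stable across processes (unlike builtin hash)
    return (base * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1)


def discover_all_motifs(
    fp_groups: list[tuple[str, list]],
    bg: motif_engine.BackgroundModel,
    config: PipelineConfig,
) -> list[tuple[PSSM, list]]:
    """Run calibrated ZOOPS discovery over all footprinting groups.
    Returns (pssm, igr list of the group) pairs."""
    rng = np.random.default_rng(_derive_seed(config.seed, "calib"))
    profiles = []
    for _ in range(min(config.calib_profiles, len(fp_groups))):
        gid, igrs = fp_groups[int(rng.integers(len(fp_groups)))]
        profiles.extend([[i.length for i in igrs]] * config.calib_null_per_profile)
    calib = motif_engine.calibrate_null(
        bg, config.discovery_widths, profiles, seed=_derive_seed(config.seed, "calibrate")
    )
    out: list[tuple[PSSM, list]] = []
    for gid, igrs in fp_groups:
        seqs = [i.sequence for i in igrs]
        found = motif_engine.discover_motifs_zoops(
            seqs,
            bg,
            nmotifs=config.nmotifs,
            widths=config.discovery_widths,
            evalue_max=config.evalue_max,
            calibration=calib,
            seed=_derive_seed(config.seed, f"disc:{gid}"),
            motif_prefix=gid,
        )
        for dm in found:
            out.append((dm.pssm, igrs))
    logger.info("discovered %d motifs from %d groups", len(out), len(fp_groups))
    return out


def cluster_discovered_motifs(
    motifs: list[PSSM],
    hits: dict[str, list[motif_engine.MotifHit]],
    config: PipelineConfig,
) -> tuple[list[MotifFamilyCluster], dict[frozenset, float]]:
    """Overlap-prefiltered pairwise comparison, BH adjustment, and
    single-linkage clustering of the discovered motifs."""
    by_id = {m.motif_id: m for m in motifs}
    keysets = {
        mid: {motif_engine.hit_key(h, by_id[mid].width, config.hit_bin) for h in hs}
        for mid, hs in hits.items()
        if mid in by_id
    }
    candidates = []
    ids = sorted(by_id)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if motif_engine.overlap_coefficient(keysets.get(a, set()), keysets.get(b, set())) >= config.min_overlap:
                candidates.append((a, b))
    pvals = []
    for a, b in candidates:
        res = motif_engine.compare_pssms(
            by_id[a], by_id[b], n_shuffle=config.compare_shuffles,
            seed=_derive_seed(config.seed, f"cmp:{a}:{b}"),
        )
        pvals.append(res.p_value)
    qs = motif_engine.qvalues(pvals)
    pair_q = {frozenset(ab): float(q) for ab, q in zip(candidates, qs)}
    clusters = motif_engine.cluster_motifs(
        motifs, keysets, pair_q, q_max=config.pair_q_max, min_overlap=config.min_overlap
    )
    return clusters, pair_q


def run_pipeline(
    world: SyntheticWorld,
    config: PipelineConfig | None = None,
    gold: GoldStandard | None = None,
) -> PipelineResult:
    """Run the full inference workflow on a (synthetic or loaded) world.

    If ``gold`` is given, the expression-consensus cutoff is chosen by the
    precision-targeted rule; otherwise the default score cutoff applies.
    """
    config = config or PipelineConfig()
    target = world.target_genome

    # 1. IGRs and footprinting groups
    igrs_by_genome = {
        g: genome_io.extract_upstream_igrs(
            world.annotations[g], world.replicon_seqs[g], min_len=config.min_igr_len
        )
        for g in world.genome_ids
    }
    all_igrs = [i for igrs in igrs_by_genome.values() for i in igrs]
    fp_groups = genome_io.assemble_footprinting_groups(
        world.ortholog_groups, all_igrs, target, min_seqs=config.min_group_seqs
    )
    bg = motif_engine.train_background([i.sequence for i in all_igrs], order=config.bg_order)

    # 2. de novo motifs
    discovered = discover_all_motifs(fp_groups, bg, config)
    motifs = [m for m, _ in discovered]

    # 3. target-genome hits and motif clustering
    target_igrs = igrs_by_genome[target]
    target_igr_seqs = {i.gene_id: i.sequence for i in target_igrs}
    hits: dict[str, list[motif_engine.MotifHit]] = {}
    for m in motifs:
        hits[m.motif_id] = motif_engine.scan_for_hits(m, target_igrs, bg, p_max=config.hit_p_max)
    clusters, _ = cluster_discovered_motifs(motifs, hits, config)

    member_pssms = {m.motif_id: m for m in motifs}
    expr_std = expr_mod.standardize_rows(world.expression)

    # 4. biclusters per motif cluster with enough target genes; a motif
    # cluster may yield several modules (single-linkage clustering can chain
    # distinct regulons into one hit union, which the refinement then
    # separates), and each module gets its own representative PSSM rebuilt
    # from the member hits on the module's genes
    cluster_pssms: dict[str, PSSM] = {}
    occurrences: dict[str, pd.DataFrame] = {}
    biclusters: list[Bicluster] = []
    bc_counter = 0
    null_cache: dict = {}
    igr_seqs_by_genome = {
        g: {i.gene_id: i.sequence for i in igrs_by_genome[g]} for g in world.genome_ids
    }
    for cl in clusters:
        genes = {h.gene_id for m in cl.members for h in hits.get(m, [])}
        if len(genes) < config.min_module:
            continue
        remaining = set(genes)
        extracted = 0
        while len(remaining) >= config.min_module and extracted < config.max_modules_per_cluster:
            bc = expr_mod.refine_coexpression(
                remaining,
                expr_std,
                min_module=config.min_module,
                min_conditions=config.min_conditions,
                p_max=config.bicluster_p_max,
                seed=_derive_seed(config.seed, f"bc:{cl.cluster_id}:{extracted}"),
                cluster_id=f"C{bc_counter:03d}",
                motif_cluster_id=cl.cluster_id,
                null_cache=null_cache,
            )
            if bc is None:
                break
            remaining -= bc.genes
            extracted += 1
            # representative motif: the member covering most module genes
            rep_member = max(
                cl.members,
                key=lambda m: (len({h.gene_id for h in hits.get(m, [])} & bc.genes), m),
            )
            w = member_pssms[rep_member].width
            sites = []
            for h in hits.get(rep_member, []):
                if h.gene_id not in bc.genes:
                    continue
                seq = target_igr_seqs.get(h.gene_id)
                if seq is None or h.offset + w > len(seq):
                    continue
                frag = seq[h.offset : h.offset + w]
                if h.strand == "-":
                    frag = genome_io.revcomp(frag)
                sites.append(frag)
            if len(sites) < 2:
                continue
            rep = motif_engine.build_pssm(sites, motif_id=bc.cluster_id, source="rebuilt")
            bc_counter += 1
            biclusters.append(bc)
            cluster_pssms[bc.cluster_id] = rep
            # cross-genome occurrence and species PSSMs for this module
            hits_by_genome: dict[str, dict[str, float]] = {}
            for g in world.genome_ids:
                ghits = motif_engine.scan_for_hits(rep, igrs_by_genome[g], bg, p_max=config.hit_p_max)
                best: dict[str, float] = {}
                g_sites = []
                for h in ghits:
                    if h.gene_id not in best or h.p_value < best[h.gene_id]:
                        best[h.gene_id] = h.p_value
                    seq = igr_seqs_by_genome[g].get(h.gene_id)
                    if seq is None or h.offset + rep.width > len(seq):
                        continue
                    frag = seq[h.offset : h.offset + rep.width]
                    if h.strand == "-":
                        frag = genome_io.revcomp(frag)
                    g_sites.append(frag)
                hits_by_genome[g] = best
                if g_sites and g not in cl.species_pssms:
                    cl.species_pssms[g] = motif_engine.build_pssm(
                        g_sites, motif_id=f"{cl.cluster_id}_{g}", source="rebuilt"
                    )
            occurrences[bc.cluster_id] = tf_linking.motif_occurrence_vectors(
                hits_by_genome, world.ortholog_groups, world.genome_ids
            )

    if not biclusters:
        empty = network.RegulatoryNetwork()
        return PipelineResult(
            biclusters=[], motif_clusters=clusters, cluster_pssms={}, rankings={}, scores={},
            core=empty, merged=empty, consensus_edges=[], consensus_cutoff=None,
            expression_std=expr_std, summary=network.summarize(empty),
        )

    # 5. TF records
    tf_ids = list(world.tf_table["tf_id"])
    presence = genome_io.tf_presence_matrix(tf_ids, world.ortholog_groups, world.genome_ids, target)
    tfs = [
        TFRecord(
            tf_id=row.tf_id,
            dbd_family=row.dbd_family,
            replicon_id=row.replicon,
            gene_index=int(row.gene_index),
            presence=presence.loc[row.tf_id],
        )
        for row in world.tf_table.itertuples(index=False)
    ]
    target_genes = world.annotations[target]

    # 6. DBD q-table and permutation nulls
    qtable = tf_linking.library_qvalues(
        cluster_pssms, world.library, n_shuffle=config.compare_shuffles,
        seed=_derive_seed(config.seed, "qtable"),
    )
    null_kwargs = dict(
        matrix=expr_std, genes=target_genes, qtable=qtable,
        occurrences=occurrences, target_genome=target, n=config.n_null,
    )
    nulls = {
        c: tf_linking.build_nulls(
            c, tfs, biclusters, seed=_derive_seed(config.seed, f"null:{c}"), **null_kwargs
        )
        for c in ("corr", "prox", "dbd", "pc")
    }

    # 7. score and rank
    scores: dict[str, list[TFClusterScore]] = {}
    rankings: dict[str, list[TFClusterScore]] = {}
    for bc in biclusters:
        occ = occurrences.get(bc.cluster_id)
        pair_scores = [
            tf_linking.score_pair(tf, bc, expr_std, target_genes, qtable, occ, target, nulls)
            for tf in tfs
        ]
        scores[bc.cluster_id] = pair_scores
        rankings[bc.cluster_id] = tf_linking.rank_tfs_for_cluster(pair_scores)

    # 8. operon extension and core network
    operon_pairs = expr_mod.predict_operons_by_distance(target_genes, max_gap=config.operon_max_gap)
    extended = {
        bc.cluster_id: expr_mod.operon_extend(bc.genes, operon_pairs, expr_std, r_min=config.operon_r_min)
        - bc.genes
        for bc in biclusters
    }
    core = network.build_core_network(biclusters, rankings, extended, matrix=expr_std)

    # 9. expression consensus
    clr = cns.clr_scores(expr_std, tf_ids)
    trees = cns.tree_importance_scores(expr_std, tf_ids, seed=_derive_seed(config.seed, "trees"))
    p_clr = cns.scores_to_pvalues(
        clr, matrix=expr_std, scorer=lambda m, t: cns.clr_scores(m, t),
        tf_ids=tf_ids, n_perm=config.n_perm_consensus, seed=_derive_seed(config.seed, "pclr"),
    )
    p_trees = cns.scores_to_pvalues(
        trees, matrix=expr_std,
        scorer=lambda m, t: cns.tree_importance_scores(m, t, seed=_derive_seed(config.seed, "treesnull")),
        tf_ids=tf_ids, n_perm=config.n_perm_consensus, seed=_derive_seed(config.seed, "ptrees"),
    )
    cons_edges = cns.combine_rexp({"clr": p_clr, "trees": p_trees})
    if gold is not None:
        cutoff = cns.threshold_by_precision(cons_edges, gold, target_precision=config.target_precision)
    else:
        cutoff = config.default_cutoff
    kept = [] if cutoff is None else [e for e in cons_edges if e.r_exp >= cutoff]
    # operon-extend expression predictions per TF
    ext_edges = list(kept)
    by_tf: dict[str, set[str]] = {}
    for e in kept:
        by_tf.setdefault(e.tf_id, set()).add(e.target_id)
    for tf, targets in by_tf.items():
        grown = expr_mod.operon_extend(targets, operon_pairs, expr_std, r_min=config.operon_r_min)
        base = min(e.r_exp for e in kept if e.tf_id == tf)
        for t in grown - targets:
            ext_edges.append(cns.ConsensusEdge(tf_id=tf, target_id=t, p_values=(None, None, None), r_exp=base))

    merged = network.merge_networks(core, ext_edges)
    summary = network.summarize(merged)
    summary["n_motif_clusters"] = len(clusters)
    summary["n_biclusters"] = len(biclusters)
    return PipelineResult(
        biclusters=biclusters,
        motif_clusters=clusters,
        cluster_pssms=cluster_pssms,
        rankings=rankings,
        scores=scores,
        core=core,
        merged=merged,
        consensus_edges=cons_edges,
        consensus_cutoff=cutoff,
        expression_std=expr_std,
        summary=summary,
    )


# ---------------------------------------------------------------------------
# Evaluation helpers against synthetic ground truth
# ---------------------------------------------------------------------------


def true_tf_of_clusters(result: PipelineResult, world: SyntheticWorld) -> dict[str, str]:
    """Map each bicluster to the planted TF whose regulon overlaps its gene
    set the most (ties to the lexicographically first TF)."""
    out = {}
    for bc in result.biclusters:
        counts = Counter()
        for tf, members in world.truth.regulons.items():
            counts[tf] = len(bc.genes & members)
        best = max(sorted(counts), key=lambda tf: counts[tf])
        if counts[best] > 0:
            out[bc.cluster_id] = best
    return out


def rank1_accuracy(
    result: PipelineResult,
    world: SyntheticWorld,
    corr_only: bool = False,
    top_k: int = 1,
) -> float:
    """Fraction of truth-mappable clusters whose true TF is ranked within
    ``top_k``.  With ``corr_only``, re-rank using the correlation criterion
    alone (the other three p-values forced to 1)."""
    truth_map = true_tf_of_clusters(result, world)
    if not truth_map:
        return 0.0
    correct = 0
    for cid, true_tf in truth_map.items():
        pair_scores = result.scores[cid]
        if corr_only:
            pair_scores = [
                TFClusterScore(
                    tf_id=s.tf_id, cluster_id=s.cluster_id,
                    corr_mean=s.corr_mean, p_corr=s.p_corr,
                    prox_min=s.prox_min, p_prox=1.0,
                    dbd_score=s.dbd_score, p_dbd=1.0,
                    phylo_corr=s.phylo_corr, p_pc=1.0,
                )
                for s in pair_scores
            ]
        ranked = tf_linking.rank_tfs_for_cluster(pair_scores, top_k=top_k)
        if true_tf in [s.tf_id for s in ranked[:top_k]]:
            correct += 1
    return correct / len(truth_map)


def evaluate_against_gold(result: PipelineResult, gold: GoldStandard) -> dict[str, float]:
    preds = result.merged.interaction_set()
    p = precision(preds, gold)
    return {
        "precision": 0.0 if p is None else p,
        "recall": recall(preds, gold),
        "n_predictions": float(len(preds)),
    }
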