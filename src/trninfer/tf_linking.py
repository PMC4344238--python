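"""Linking transcription factors to co-regulated gene clusters.

Each candidate (TF, cluster) pair is scored on four criteria:

* ``corr``  — mean |Pearson r| between the TF's expression profile and each
  cluster member over the bicluster's condition subset;
* ``prox``  — minimum genomic distance (in genes) between the TF and any
  same-replicon cluster member;
* ``dbd``   — similarity of the cluster motif to reference motifs of TFs in
  the same DNA-binding-domain family, as -log10 of the best q-value;
* ``pc``    — phylogenetic correlation between the motif's cross-species
  occurrence profile and the TF's cross-species presence.

Criterion values are converted to empirical p-values against permutation
nulls of 1000 randomly paired scores and combined as
``R = -log10(p_corr * p_prox * p_dbd * p_pc)``.  A criterion that is
undefined for a pair (TF off-replicon, family absent from the library,
zero-variance presence, TF not on the array) contributes p = 1, i.e.
neutral evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from trninfer.expression import Bicluster
from trninfer.genome_io import GeneRecord
from trninfer.motif_engine import PSSM, compare_pssms, qvalues

P_FLOOR_N = 1000  # permutation null size


@dataclass
class TFRecord:
    tf_id: str
    dbd_family: str = ""
    replicon_id: str = ""
    gene_index: int = -1
    presence: pd.Series | None = None  # binary vector over genomes


@dataclass
class ReferenceMotifLibrary:
    """Reference motifs with known binding TFs and their DBD families."""

    entries: list[tuple[PSSM, str, str]]  # (pssm, tf_name, dbd_family)

    def families(self) -> set[str]:
        return {fam for _, _, fam in self.entries}


@dataclass
class TFClusterScore:
    tf_id: str
    cluster_id: str
    corr_mean: float | None
    p_corr: float
    prox_min: int | None
    p_prox: float
    dbd_score: float | None
    p_dbd: float
    phylo_corr: float | None
    p_pc: float

    @property
    def r_score(self) -> float:
        return r_score(self.p_corr, self.p_prox, self.p_dbd, self.p_pc)


@dataclass
class PermutationNull:
    criterion: str  # corr | prox | dbd | pc
    values: np.ndarray
    seed: int


# ---------------------------------------------------------------------------
# Criterion statistics
# ---------------------------------------------------------------------------


def corr_mean(tf: TFRecord, bicluster: Bicluster, matrix: pd.DataFrame) -> float | None:
    """Average |Pearson r| between the TF and each cluster gene over the
    bicluster's condition subset.  The TF is excluded from the gene list if
    it is itself a member; None if the TF is not on the array."""
    if tf.tf_id not in matrix.index:
        return None
    conds = sorted(bicluster.conditions)
    genes = sorted(g for g in bicluster.genes if g != tf.tf_id and g in matrix.index)
    if not genes or len(conds) < 2:
        return None
    t = matrix.loc[tf.tf_id, conds].to_numpy(dtype=float)
    if t.std() == 0:
        return 0.0
    vals = []
    for g in genes:
        x = matrix.loc[g, conds].to_numpy(dtype=float)
        if x.std() == 0:
            continue
        vals.append(abs(float(np.corrcoef(t, x)[0, 1])))
    return float(np.mean(vals)) if vals else None


def prox_min(tf: TFRecord, cluster_genes: set[str], genes: list[GeneRecord]) -> int | None:
    """Minimum distance in number of genes between the TF and any cluster
    member on the same replicon; 0 if the TF is a member; None if no member
    shares a replicon."""
    index = {g.gene_id: g for g in genes}
    if tf.tf_id in cluster_genes:
        return 0
    best = None
    for gid in cluster_genes:
        rec = index.get(gid)
        if rec is None or rec.replicon_id != tf.replicon_id:
            continue
        d = abs(rec.gene_index - tf.gene_index)
        if best is None or d < best:
            best = d
    return best


def library_qvalues(
    cluster_pssms: dict[str, PSSM],
    lib: ReferenceMotifLibrary,
    n_shuffle: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare every cluster PSSM against every library PSSM and BH-adjust
    the comparison p-values over the full set.  Returns a long DataFrame
    (cluster_id, tf_name, dbd_family, p, q)."""
    rows = []
    for k, (cid, cp) in enumerate(sorted(cluster_pssms.items())):
        for j, (lp, tf_name, fam) in enumerate(lib.entries):
            res = compare_pssms(cp, lp, n_shuffle=n_shuffle, seed=seed + 7919 * k + j)
            rows.append((cid, tf_name, fam, res.p_value, res.statistic))
    df = pd.DataFrame(rows, columns=["cluster_id", "tf_name", "dbd_family", "p", "statistic"])
    if not df.empty:
        df["q"] = qvalues(df["p"].to_numpy())
    else:
        df["q"] = []
    return df


def dbd_score(tf: TFRecord, cluster_id: str, qtable: pd.DataFrame) -> float | None:
    """-log10 of the smallest q among comparisons of the cluster motif to
    library motifs of the TF's DBD family; None if the family is absent or
    the TF has no family label."""
    if not tf.dbd_family:
        return None
    sub = qtable[(qtable["cluster_id"] == cluster_id) & (qtable["dbd_family"] == tf.dbd_family)]
    if sub.empty:
        return None
    qmin = float(sub["q"].min())
    return float(-np.log10(max(qmin, 1e-300)))


def motif_occurrence_vectors(
    hits_by_genome: dict[str, dict[str, float]],
    ortholog_groups: list,
    genome_ids: list[str],
) -> pd.DataFrame:
    """Per-genome vectors over ortholog groups of -log10(best hit p-value)
    for one motif (0 where the motif has no hit in that group's IGRs)."""
    mat = pd.DataFrame(0.0, index=[g.group_id for g in ortholog_groups], columns=genome_ids)
    gene_to_group: dict[tuple[str, str], str] = {}
    for grp in ortholog_groups:
        for genome, gene_list in grp.members.items():
            for gid in gene_list:
                gene_to_group[(genome, gid)] = grp.group_id
    for genome, gene_ps in hits_by_genome.items():
        if genome not in mat.columns:
            continue
        for gene, p in gene_ps.items():
            grp = gene_to_group.get((genome, gene))
            if grp is None:
                continue
            val = -np.log10(max(p, 1e-300))
            if val > mat.at[grp, genome]:
                mat.at[grp, genome] = val
    return mat


def phylo_corr(
    tf: TFRecord,
    occurrence: pd.DataFrame,
    target_genome: str,
) -> float | None:
    """Correlation of the motif-occurrence correlation profile with TF
    presence across genomes.

    Step 1: for each genome, Pearson r between its motif-occurrence vector
    (over ortholog groups) and the target genome's.  Step 2: Pearson r
    between those per-genome values and the TF presence vector.  None if
    either vector has zero variance."""
    if tf.presence is None:
        return None
    genomes = [g for g in occurrence.columns if g in tf.presence.index]
    tvec = occurrence[target_genome].to_numpy(dtype=float)
    if tvec.std() == 0:
        return None
    m = []
    for g in genomes:
        v = occurrence[g].to_numpy(dtype=float)
        m.append(float(np.corrcoef(v, tvec)[0, 1]) if v.std() > 0 else 0.0)
    m = np.asarray(m)
    pres = tf.presence.loc[genomes].to_numpy(dtype=float)
    if m.std() == 0 or pres.std() == 0:
        return None
    return float(np.corrcoef(m, pres)[0, 1])


# ---------------------------------------------------------------------------
# Permutation p-values
# ---------------------------------------------------------------------------


def permutation_pvalue(observed: float, null: PermutationNull, direction: str) -> float:
    """Empirical p-value: fraction of null values at least as extreme as the
    observation (``ge`` for scores, ``le`` for distances), floored at
    1/(n+1) so p is never exactly 0."""
    vals = null.values
    n = vals.size
    if direction == "ge":
        count = int((vals >= observed - 1e-12).sum())
    elif direction == "le":
        count = int((vals <= observed + 1e-12).sum())
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return max(count / n, 1.0 / (n + 1))


def build_nulls(
    criterion: str,
    tfs: list[TFRecord],
    clusters: list[Bicluster],
    matrix: pd.DataFrame | None = None,
    genes: list[GeneRecord] | None = None,
    qtable: pd.DataFrame | None = None,
    occurrences: dict[str, pd.DataFrame] | None = None,
    target_genome: str | None = None,
    n: int = 1000,
    seed: int = 0,
) -> PermutationNull:
    """Generate a permutation null for one criterion by re-scoring randomly
    paired TFs and clusters (a random family against a random cluster motif
    for ``dbd``).  Pairing random TFs with the actual clusters keeps the
    null faithful to the data's structure — in particular, a coherent
    cluster concentrates the mean |corr| of even an unrelated TF, which a
    null built from arbitrary gene sets would miss.  Undefined draws are
    resampled."""
    rng = np.random.default_rng(seed)
    values: list[float] = []
    families = sorted({t.dbd_family for t in tfs if t.dbd_family})
    guard = 0
    while len(values) < n:
        guard += 1
        if guard > 50 * n:
            raise RuntimeError(f"cannot populate {criterion} null (criterion mostly undefined)")
        tf = tfs[rng.integers(len(tfs))]
        cl = clusters[rng.integers(len(clusters))]
        if criterion == "corr":
            if matrix is None:
                raise ValueError("corr null needs the expression matrix")
            v = corr_mean(tf, cl, matrix)
        elif criterion == "prox":
            v = prox_min(tf, cl.genes, genes or [])
        elif criterion == "dbd":
            if qtable is None or qtable.empty or not families:
                raise ValueError("dbd null needs a library q-table")
            fam = families[rng.integers(len(families))]
            fake_tf = TFRecord(tf_id="null", dbd_family=fam)
            v = dbd_score(fake_tf, cl.cluster_id, qtable)
        elif criterion == "pc":
            if occurrences is None or target_genome is None:
                raise ValueError("pc null needs occurrence vectors")
            occ = occurrences.get(cl.cluster_id)
            if occ is None:
                occ = occurrences.get(cl.motif_cluster_id)
            v = phylo_corr(tf, occ, target_genome) if occ is not None else None
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        if v is not None:
            values.append(float(v))
    return PermutationNull(criterion=criterion, values=np.asarray(values), seed=seed)


def r_score(p_corr: float, p_prox: float, p_dbd: float, p_pc: float) -> float:
    """Combined evidence score: -log10 of the product of the four p-values."""
    for p in (p_corr, p_prox, p_dbd, p_pc):
        if not (0 < p <= 1):
            raise ValueError(f"p-values must be in (0, 1], got {p}")
    return float(-(np.log10(p_corr) + np.log10(p_prox) + np.log10(p_dbd) + np.log10(p_pc)))


def score_pair(
    tf: TFRecord,
    bicluster: Bicluster,
    matrix: pd.DataFrame,
    genes: list[GeneRecord],
    qtable: pd.DataFrame | None,
    occurrence: pd.DataFrame | None,
    target_genome: str,
    nulls: dict[str, PermutationNull],
) -> TFClusterScore:
    """Score one (TF, cluster) pair on all four criteria."""
    cm = corr_mean(tf, bicluster, matrix)
    pm = prox_min(tf, bicluster.genes, genes)
    ds = dbd_score(tf, bicluster.cluster_id, qtable) if qtable is not None else None
    pc = phylo_corr(tf, occurrence, target_genome) if occurrence is not None else None
    p_corr = 1.0 if cm is None else permutation_pvalue(cm, nulls["corr"], "ge")
    p_prox = 1.0 if pm is None else permutation_pvalue(pm, nulls["prox"], "le")
    p_dbd = 1.0 if ds is None else permutation_pvalue(ds, nulls["dbd"], "ge")
    p_pc = 1.0 if pc is None else permutation_pvalue(pc, nulls["pc"], "ge")
    return TFClusterScore(
        tf_id=tf.tf_id,
        cluster_id=bicluster.cluster_id,
        corr_mean=cm,
        p_corr=p_corr,
        prox_min=pm,
        p_prox=p_prox,
        dbd_score=ds,
        p_dbd=p_dbd,
        phylo_corr=pc,
        p_pc=p_pc,
    )


def rank_tfs_for_cluster(scores: list[TFClusterScore], top_k: int = 3) -> list[TFClusterScore]:
    """Rank candidate regulators of a cluster: descending combined score,
    ties broken by (p_dbd, p_corr, tf_id).  The rank-1 TF is the cluster's
    network regulator."""
    if not scores:
        raise ValueError("need at least one scored TF")
    ranked = sorted(scores, key=lambda s: (-s.r_score, s.p_dbd, s.p_corr, s.tf_id))
    return ranked[:top_k]


def scores_table(scores: list[TFClusterScore]) -> pd.DataFrame:
    """Long table of all pair scores, p-values, and combined scores."""
    rows = []
    for s in scores:
        rows.append(
            {
                "tf_id": s.tf_id,
                "cluster_id": s.cluster_id,
                "corr_mean": s.corr_mean,
                "p_corr": s.p_corr,
                "prox_min": s.prox_min,
                "p_prox": s.p_prox,
                "dbd_score": s.dbd_score,
                "p_dbd": s.p_dbd,
                "phylo_corr": s.phylo_corr,
                "p_pc": s.p_pc,
                "r_score": s.r_score,
            }
        )
    return pd.DataFrame(rows)
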