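"""Expression-only network inference: a CLR-style mutual-information scorer,
a tree-ensemble importance scorer, adapters for externally computed ranked
edge lists, permutation p-values per approach, and the consensus combiner

    R_exp = (1/3) * sum_approaches( -log10 p )

with the divisor fixed at 3 (the design assumes up to three approaches;
absent approaches contribute 0).  A precision-targeted score threshold is
derived from a gold standard over prefixes of the ranked consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MAX_EDGES = 50_000  # ranked lists are truncated to this many edges


@dataclass
class RankedEdgeList:
    approach_id: str
    edges: pd.DataFrame  # columns: tf, target, score, rank (1-based, descending score)

    def __post_init__(self) -> None:
        df = self.edges
        if not df.empty and not (df["score"].diff().dropna() <= 1e-12).all():
            raise ValueError("edges must be sorted by descending score")


def _to_ranked(approach_id: str, rows: list[tuple[str, str, float]]) -> RankedEdgeList:
    df = pd.DataFrame(rows, columns=["tf", "target", "score"])
    df = df.sort_values(["score", "tf", "target"], ascending=[False, True, True], kind="mergesort")
    df = df.head(MAX_EDGES).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return RankedEdgeList(approach_id=approach_id, edges=df)


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    bins = np.empty(x.size, dtype=np.int64)
    bins[order] = (np.arange(x.size) * n_bins) // x.size
    return bins


def _mutual_information(bx: np.ndarray, by: np.ndarray, n_bins: int) -> float:
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).reshape(n_bins, n_bins)
    n = joint.sum()
    pj = joint / n
    px = pj.sum(axis=1, keepdims=True)
    py = pj.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pj * np.log(pj / (px * py))
    return float(np.nansum(terms))


def clr_scores(matrix: pd.DataFrame, tf_ids: list[str], n_bins: int = 10) -> RankedEdgeList:
    """Context-likelihood-of-relatedness scores.

    Mutual information between each TF and each gene is estimated on
    equal-frequency bins; each MI value is background-corrected by z-scoring
    against the TF's row and the gene's column of the MI matrix, and the
    edge score is ``sqrt(max(z_tf,0)^2 + max(z_gene,0)^2)``.  Self-edges are
    excluded; output edges are directed TF -> target."""
    if matrix.shape[1] < 20:
        warnings.warn("fewer than 20 conditions; MI estimates will be noisy")
    tfs = [t for t in tf_ids if t in matrix.index]
    genes = list(matrix.index)
    binned = {g: _equal_frequency_bins(matrix.loc[g].to_numpy(dtype=float), n_bins) for g in genes}
    mi = np.zeros((len(tfs), len(genes)))
    for i, tf in enumerate(tfs):
        for j, g in enumerate(genes):
            if g == tf:
                mi[i, j] = np.nan
                continue
            mi[i, j] = _mutual_information(binned[tf], binned[g], n_bins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z_tf = (mi - np.nanmean(mi, axis=1, keepdims=True)) / np.nanstd(mi, axis=1, keepdims=True)
        z_g = (mi - np.nanmean(mi, axis=0, keepdims=True)) / np.nanstd(mi, axis=0, keepdims=True)
    score = np.sqrt(np.maximum(z_tf, 0) ** 2 + np.maximum(z_g, 0) ** 2)
    rows = [
        (tf, genes[j], float(score[i, j]))
        for i, tf in enumerate(tfs)
        for j in range(len(genes))
        if np.isfinite(score[i, j]) and genes[j] != tf
    ]
    return _to_ranked("clr", rows)


def tree_importance_scores(
    matrix: pd.DataFrame,
    tf_ids: list[str],
    seed: int = 0,
    n_estimators: int = 50,
) -> RankedEdgeList:
    """Tree-ensemble feature importances, one randomized regression forest
    per target gene with the TF expression rows as features."""
    from sklearn.ensemble import ExtraTreesRegressor

    tfs = [t for t in tf_ids if t in matrix.index]
    if len(tfs) < 2:
        raise ValueError("need at least 2 TFs on the array")
    x_all = matrix.loc[tfs].to_numpy(dtype=float).T  # conditions x TFs
    rows: list[tuple[str, str, float]] = []
    rng = np.random.default_rng(seed)
    for target in matrix.index:
        y = matrix.loc[target].to_numpy(dtype=float)
        if y.std() == 0:
            continue
        feat_tfs = [t for t in tfs if t != target]
        if len(feat_tfs) < 2:
            continue
        cols = [tfs.index(t) for t in feat_tfs]
        model = ExtraTreesRegressor(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        model.fit(x_all[:, cols], y)
        for t, imp in zip(feat_tfs, model.feature_importances_):
            rows.append((t, target, float(imp)))
    return _to_ranked("trees", rows)


def import_ranked_list(path, approach_id: str) -> RankedEdgeList:
    """Read an external TSV edge list (tf, target, score); duplicates keep
    the maximum score with a warning; truncated to the top 50,000."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    expected = {"tf", "target", "score"}
    df.columns = [c.lower() for c in df.columns]
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: expected columns tf, target, score")
    bad = df["score"].isna() | df["tf"].isna() | df["target"].isna()
    if bad.any():
        raise ValueError(f"{path}: malformed row at line {int(bad.idxmax()) + 2}")
    if df.duplicated(["tf", "target"]).any():
        warnings.warn(f"{approach_id}: duplicate (tf, target) rows; keeping max score")
        df = df.groupby(["tf", "target"], as_index=False)["score"].max()
    return _to_ranked(approach_id, list(df[["tf", "target", "score"]].itertuples(index=False, name=None)))


def scores_to_pvalues(
    ranked: RankedEdgeList,
    matrix: pd.DataFrame | None = None,
    scorer=None,
    tf_ids: list[str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    universe: int | None = None,
) -> dict[tuple[str, str], float]:
    """Empirical p-value per edge: fraction of ``n_perm`` random TF-target
    scores at least as large, floored at 1/(n_perm+1).

    For built-in scorers, random scores come from re-running the scorer on a
    within-row-permuted expression matrix (TF-target dependence destroyed,
    marginals preserved).  For imported lists, random pair scores are drawn
    from the empirical list scores with probability N/universe and are 0
    otherwise."""
    rng = np.random.default_rng(seed)
    if scorer is not None:
        if matrix is None or tf_ids is None:
            raise ValueError("built-in null needs matrix and tf_ids")
        perm = matrix.copy()
        vals = perm.to_numpy()
        for i in range(vals.shape[0]):
            vals[i] = vals[i, rng.permutation(vals.shape[1])]
        null_list = scorer(pd.DataFrame(vals, index=perm.index, columns=perm.columns), tf_ids)
        pool = null_list.edges["score"].to_numpy(dtype=float)
        null = rng.choice(pool, size=n_perm, replace=True) if pool.size else np.zeros(n_perm)
    else:
        scores = ranked.edges["score"].to_numpy(dtype=float)
        n = scores.size
        if universe is None:
            tfs = ranked.edges["tf"].nunique()
            targets = ranked.edges["target"].nunique()
            universe = max(tfs * targets, n)
        inlist = rng.random(n_perm) < (n / universe)
        null = np.where(inlist, rng.choice(scores, size=n_perm, replace=True), 0.0)
    null_sorted = np.sort(null)
    out: dict[tuple[str, str], float] = {}
    for row in ranked.edges.itertuples(index=False):
        count = n_perm - int(np.searchsorted(null_sorted, row.score - 1e-12, side="left"))
        out[(row.tf, row.target)] = max(count / n_perm, 1.0 / (n_perm + 1))
    return out


@dataclass(frozen=True)
class ConsensusEdge:
    tf_id: str
    target_id: str
    p_values: tuple  # per-approach p or None
    r_exp: float


def combine_rexp(pmaps: dict[str, dict[tuple[str, str], float]]) -> list[ConsensusEdge]:
    """Combine up to three approach p-value maps into consensus edges,
    averaging -log10 p with the fixed divisor 3; an edge absent from an
    approach contributes 0 for that slot, and edges absent from every
    approach are not emitted."""
    approaches = sorted(pmaps)
    if not (1 <= len(approaches) <= 3):
        raise ValueError("combine_rexp accepts 1-3 approaches")
    edges: set[tuple[str, str]] = set()
    for m in pmaps.values():
        edges |= set(m)
    out = []
    for tf, tgt in sorted(edges):
        ps = tuple(pmaps[a].get((tf, tgt)) for a in approaches)
        total = sum(-np.log10(p) for p in ps if p is not None)
        out.append(ConsensusEdge(tf_id=tf, target_id=tgt, p_values=ps, r_exp=float(total / 3.0)))
    out.sort(key=lambda e: (-e.r_exp, e.tf_id, e.target_id))
    return out


def threshold_by_precision(
    edges: list[ConsensusEdge],
    gold,
    target_precision: float = 0.95,
    interval: int = 100,
) -> float | None:
    """Largest prefix (in ``interval`` steps) of the ranked consensus whose
    restricted precision meets ``target_precision``; returns the consensus
    score at that prefix boundary, or None if no prefix qualifies."""
    from trninfer.evaluation import restricted_precision

    best_cutoff = None
    n = len(edges)
    sizes = list(range(interval, n + 1, interval))
    if not sizes or sizes[-1] != n:
        sizes.append(n)
    for k in sizes:
        preds = {(e.tf_id, e.target_id) for e in edges[:k]}
        prec = restricted_precision(preds, gold)
        if prec is not None and prec >= target_precision:
            best_cutoff = edges[k - 1].r_exp
    return best_cutoff
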