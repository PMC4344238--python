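"""Expression processing: row standardization, condition-specific
co-expression refinement of motif-based gene sets (biclustering), and
operon-based target extension.

Expression matrices are pandas DataFrames with genes as rows and
conditions as columns, assumed log2-scale normalized.  Correlations are
Pearson; absolute values are used for co-expression throughout, since
repression produces anti-correlated profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class Bicluster:
    """A refined co-expression module: gene subset + condition subset."""

    cluster_id: str
    genes: set[str]
    conditions: set[str]
    mean_abs_pairwise_corr: float
    motif_cluster_id: str | None = None
    p_value: float = 1.0


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a TSV expression matrix (first column gene ids, header = condition ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def standardize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row (ddof=1); constant rows are dropped with a warning."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 conditions to standardize")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("dropping %d constant expression row(s)", int((~keep).sum()))
    values = values[keep]
    sd = sd[keep]
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


def _mean_abs_pairwise_corr(x: np.ndarray) -> float:
    """Mean |Pearson r| over gene pairs; rows = genes, columns = conditions."""
    g = x.shape[0]
    if g < 2 or x.shape[1] < 2:
        return 0.0
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(x)
    iu = np.triu_indices(g, k=1)
    vals = np.abs(c[iu])
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else 0.0


def _loo_condition_scores(x: np.ndarray) -> np.ndarray:
    """Mean |pairwise corr| after leaving out each condition, fully
    vectorised via sufficient statistics.  Returns an array of length
    n_conditions."""
    g, n = x.shape
    s1 = x.sum(axis=1)  # (g,)
    s2 = (x**2).sum(axis=1)
    sxy = x @ x.T  # (g, g)
    m = n - 1
    xt = x.T  # (n, g)
    s1c = s1[None, :] - xt  # (n, g)
    cov = sxy[None, :, :] - xt[:, :, None] * xt[:, None, :] - s1c[:, :, None] * s1c[:, None, :] / m
    var = (s2[None, :] - xt**2) - s1c**2 / m
    denom = np.sqrt(var[:, :, None] * var[:, None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(cov / denom)
    iu = np.triu_indices(g, k=1)
    vals = r[:, iu[0], iu[1]]  # (n, n_pairs)
    finite = np.isfinite(vals)
    counts = finite.sum(axis=1)
    sums = np.where(finite, vals, 0.0).sum(axis=1)
    out = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return out


def _greedy_condition_refine(
    x: np.ndarray,
    min_conditions: int,
    min_improvement: float,
    batch: int = 3,
) -> tuple[np.ndarray, float]:
    """Greedy condition removal with the improvement stopping rule.

    Per iteration the leave-one-out score of every remaining condition is
    computed; up to ``batch`` conditions whose individual removal improves
    the score by more than ``min_improvement`` are dropped.  Returns (kept
    condition indices, final score)."""
    idx = np.arange(x.shape[1])
    score = _mean_abs_pairwise_corr(x)
    while idx.size > min_conditions:
        loo = _loo_condition_scores(x[:, idx])
        order = np.argsort(loo)[::-1]
        take = [c for c in order[: min(batch, idx.size - min_conditions)] if loo[c] > score + min_improvement]
        if not take:
            break
        score = float(loo[take[0]])
        idx = np.delete(idx, take)
        if len(take) > 1:
            score = _mean_abs_pairwise_corr(x[:, idx])
    return idx, score


def _corr_to_core(x: np.ndarray, conds: np.ndarray, core: list[int]) -> np.ndarray:
    """Mean |Pearson r| of every gene row to the core genes over ``conds``."""
    sub = x[:, conds]
    sd = sub.std(axis=1)
    sd_safe = np.where(sd > 0, sd, np.inf)
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd_safe[:, None]
    c = np.abs(z @ z[core].T / conds.size)
    for k, g in enumerate(core):
        c[g, k] = np.nan
    with np.errstate(invalid="ignore"):
        out = np.nanmean(c, axis=1)
    return np.where(np.isfinite(out), out, 0.0)


def _refine_core(
    x: np.ndarray,
    min_module: int,
    min_conditions: int,
    min_improvement: float,
    tau_rel: float = 0.5,
    tau_floor: float = 0.15,
    max_rounds: int = 3,
) -> tuple[list[int], np.ndarray, float]:
    """Seed-and-grow refinement of one candidate module.

    Seeds with the most-correlated gene pair (forced up to ``min_module``
    genes), then iterates: grow the core with genes whose mean |corr| to
    the core clears a relative threshold, re-select conditions by greedy
    leave-one-out removal (restarted from all conditions), and prune genes
    below the threshold (never under ``min_module``).  The relative
    threshold makes the search robust when spurious genes outnumber the
    true module in the input set.

    Returns (gene indices, condition indices, mean pairwise |corr|).
    """
    g0, n_cond = x.shape
    conds = np.arange(n_cond)
    with np.errstate(invalid="ignore"):
        r0 = np.abs(np.corrcoef(x))
    r0 = np.where(np.isfinite(r0), r0, 0.0)
    np.fill_diagonal(r0, 0.0)
    i, j = np.unravel_index(int(r0.argmax()), r0.shape)
    core: list[int] = sorted({int(i), int(j)})
    # force the core up to the minimum module size so that every refinement
    # (observed or null) scores a module of comparable gene count
    while len(core) < min(min_module, g0):
        means = r0[:, core].mean(axis=1)
        means[core] = -np.inf
        core.append(int(means.argmax()))
    core = sorted(core)
    score = _mean_abs_pairwise_corr(x[np.ix_(core, conds)])
    for _ in range(max_rounds):
        changed = False
        # condition re-selection from scratch on the current core
        new_conds, score = _greedy_condition_refine(x[core], min_conditions, min_improvement)
        if new_conds.size != conds.size or not np.array_equal(new_conds, conds):
            changed = True
        conds = new_conds
        # grow: admit genes coherent with the core over the refined conditions
        tau = max(tau_rel * score, tau_floor)
        mg = _corr_to_core(x, conds, core)
        for g in np.nonzero(mg >= tau)[0]:
            if g not in core:
                core.append(int(g))
                changed = True
        core = sorted(core)
        score = _mean_abs_pairwise_corr(x[np.ix_(core, conds)])
        # prune genes below the relative threshold (floor: min module size)
        while len(core) > min_module:
            sub = x[np.ix_(core, conds)]
            with np.errstate(invalid="ignore"):
                rr = np.abs(np.corrcoef(sub))
            rr = np.where(np.isfinite(rr), rr, 0.0)
            np.fill_diagonal(rr, np.nan)
            means = np.nanmean(rr, axis=1)
            worst = int(np.nanargmin(means))
            if means[worst] < max(tau_rel * score, tau_floor):
                core.pop(worst)
                score = _mean_abs_pairwise_corr(x[np.ix_(core, conds)])
                changed = True
            else:
                break
        if not changed:
            break
    conds, score = _greedy_condition_refine(x[core], min_conditions, min_improvement)
    return core, conds, score


_SIZE_BUCKETS = (3, 4, 5, 6, 8, 12, 18, 25, 50, 100, 200)


def _bucket_up(n: int) -> int:
    for b in _SIZE_BUCKETS:
        if n <= b:
            return b
    return _SIZE_BUCKETS[-1]


def _bucket_down(n: int) -> int:
    out = _SIZE_BUCKETS[0]
    for b in _SIZE_BUCKETS:
        if b <= n:
            out = b
    return out


def _null_refined_scores(
    all_rows: np.ndarray,
    n_start: int,
    module_size: int,
    min_conditions: int,
    min_improvement: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null distribution of the module score: the same seed-and-grow
    refinement applied to random gene sets drawn from a row-permuted copy
    of the matrix, with the module size pinned to the observed one.  Row
    permutation destroys all real co-expression (so the null cannot
    rediscover genuine modules) while replaying the refinement carries the
    optimiser's selection bias into the null."""
    perm = all_rows.copy()
    for k in range(perm.shape[0]):
        perm[k] = perm[k, rng.permutation(perm.shape[1])]
    n_genes = perm.shape[0]
    out = np.empty(n_perm)
    size = min(n_start, n_genes)
    for t in range(n_perm):
        pick = rng.choice(n_genes, size=size, replace=False)
        _, _, score = _refine_core(perm[pick], module_size, min_conditions, min_improvement)
        out[t] = score
    return out


def _null_rejects_early(
    all_rows: np.ndarray,
    observed: float,
    n_start: int,
    module_size: int,
    min_conditions: int,
    min_improvement: float,
    n_perm: int,
    p_max: float,
    rng: np.random.Generator,
) -> tuple[bool, np.ndarray | None]:
    """Incremental null evaluation: stop as soon as enough null draws meet
    the observed score to guarantee p > p_max.  Returns (rejected, null) —
    the full null array only when the module survives all draws."""
    perm = all_rows.copy()
    for k in range(perm.shape[0]):
        perm[k] = perm[k, rng.permutation(perm.shape[1])]
    n_genes = perm.shape[0]
    size = min(n_start, n_genes)
    reject_at = int(np.floor(p_max * n_perm)) + 1
    out = np.empty(n_perm)
    count = 0
    for t in range(n_perm):
        pick = rng.choice(n_genes, size=size, replace=False)
        _, _, score = _refine_core(perm[pick], module_size, min_conditions, min_improvement)
        out[t] = score
        if score >= observed - 1e-12:
            count += 1
            if count >= reject_at:
                return True, None
    return False, out


def refine_coexpression(
    gene_set: set[str],
    matrix: pd.DataFrame,
    min_module: int = 3,
    min_conditions: int = 30,
    p_max: float = 0.001,
    n_perm: int = 1000,
    seed: int = 0,
    cluster_id: str = "BC000",
    motif_cluster_id: str | None = None,
    min_improvement: float = 0.005,
    null_cache: dict | None = None,
) -> Bicluster | None:
    """Refine a candidate co-regulated gene set into a bicluster.

    The seed-and-grow search (see :func:`_refine_core`) selects the gene
    subset and the condition subset under which the set is coherently
    co-expressed; conditions are dropped greedily while each removal
    improves the mean pairwise |correlation| by more than
    ``min_improvement``.  The refined module is accepted only if at least
    ``min_module`` genes and ``min_conditions`` conditions survive and the
    permutation p-value (``n_perm`` random gene sets refined by the same
    procedure on a row-permuted matrix, matched in input and module size)
    is at most ``p_max``.  ``null_cache`` shares null distributions between
    calls with similar sizes; sizes are bucketed conservatively (input size
    rounded up, module size down).
    """
    genes = sorted(g for g in gene_set if g in matrix.index)
    if len(genes) < len(gene_set):
        logger.info(
            "dropping %d gene(s) absent from the expression matrix", len(gene_set) - len(genes)
        )
    if len(genes) < min_module:
        return None
    conditions = list(matrix.columns)
    x = matrix.loc[genes].to_numpy(dtype=float)
    core, cond_idx, score = _refine_core(x, min_module, min_conditions, min_improvement)
    final_genes = {genes[i] for i in core}
    final_conds = [conditions[i] for i in cond_idx]
    if len(final_genes) < min_module or len(final_conds) < min_conditions:
        return None
    n_start = _bucket_up(len(genes))
    module_size = max(_bucket_down(len(core)), min_module)
    key = (n_start, module_size, min_conditions, n_perm)
    null = None if null_cache is None else null_cache.get(key)
    if null is None:
        rng = np.random.default_rng(seed)
        rejected, null = _null_rejects_early(
            matrix.to_numpy(dtype=float),
            observed=score,
            n_start=n_start,
            module_size=module_size,
            min_conditions=min_conditions,
            min_improvement=min_improvement,
            n_perm=n_perm,
            p_max=p_max,
            rng=rng,
        )
        if rejected:
            return None
        if null_cache is not None:
            null_cache[key] = null
    count = int((null >= score - 1e-12).sum())
    p = max(count / n_perm, 1.0 / (n_perm + 1))
    if p > p_max:
        return None
    return Bicluster(
        cluster_id=cluster_id,
        genes=final_genes,
        conditions=set(final_conds),
        mean_abs_pairwise_corr=score,
        motif_cluster_id=motif_cluster_id,
        p_value=p,
    )


@dataclass(frozen=True)
class OperonPair:
    """A distance-based prediction that ``downstream`` is co-transcribed
    immediately after ``upstream``."""

    upstream: str
    downstream: str


def predict_operons_by_distance(genes: list, max_gap: int = 50) -> list[OperonPair]:
    """Fallback distance rule: adjacent co-strand genes with intergenic gap
    <= ``max_gap`` bp form a directed operon pair in transcription order."""
    pairs: list[OperonPair] = []
    by_replicon: dict[str, list] = {}
    for g in genes:
        by_replicon.setdefault(g.replicon_id, []).append(g)
    for recs in by_replicon.values():
        recs = sorted(recs, key=lambda g: g.start)
        for a, b in zip(recs, recs[1:]):
            if a.strand != b.strand:
                continue
            gap = b.start - a.end - 1
            if gap <= max_gap:
                if a.strand == "+":
                    pairs.append(OperonPair(a.gene_id, b.gene_id))
                else:
                    pairs.append(OperonPair(b.gene_id, a.gene_id))
    return pairs


def operon_extend(
    targets: set[str],
    operon_predictions: list[OperonPair],
    matrix: pd.DataFrame,
    r_min: float = 0.8,
) -> set[str]:
    """Transitively add downstream operon genes to a target set.

    A gene is added when a distance-based operon prediction links it
    downstream of a current target AND its Pearson correlation with that
    target over ALL conditions is at least ``r_min``.  Never removes seed
    targets; idempotent.
    """
    down: dict[str, list[str]] = {}
    for p in operon_predictions:
        down.setdefault(p.upstream, []).append(p.downstream)
    extended = set(targets)
    frontier = list(targets)
    while frontier:
        gene = frontier.pop()
        for nxt in down.get(gene, []):
            if nxt in extended:
                continue
            if gene not in matrix.index or nxt not in matrix.index:
                continue
            a = matrix.loc[gene].to_numpy(dtype=float)
            b = matrix.loc[nxt].to_numpy(dtype=float)
            if a.std() == 0 or b.std() == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if r >= r_min:
                extended.add(nxt)
                frontier.append(nxt)
    return extended
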