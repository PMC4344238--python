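"""Motif machinery: PSSM construction, de novo ZOOPS discovery, genome
scanning with exact p-values, pairwise PSSM comparison, and single-linkage
motif clustering.

The discovery/scan/comparison stages are surrogates with the same contracts
as the MEME / MAST / Tomtom steps of classical phylogenetic-footprinting
pipelines: a zero-or-one-occurrence-per-sequence (ZOOPS) mixture model fit
by EM, best-hit scanning against an exact log-odds score distribution, and
a column-correlation comparison statistic with a column-shuffle null.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

DNA = "ACGT"
_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(DNA):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)

_FREQ_FLOOR = 1e-9  # for log-odds of zero-probability cells
SCORE_GRANULARITY = 1e-3  # log2 log-odds scores are rounded to this lattice


def encode(seq: str) -> np.ndarray:
    """DNA string -> int8 array, A/C/G/T -> 0..3, anything else -> -1."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return "".join(DNA[b] if b >= 0 else "N" for b in arr)


def revcomp_encoded(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    mask = out >= 0
    out[mask] = _COMPLEMENT[out[mask]]
    return out


# ---------------------------------------------------------------------------
# Background model
# ---------------------------------------------------------------------------


@dataclass
class BackgroundModel:
    """Markov background model of intergenic sequence.

    ``cond[k]`` holds conditional frequencies P(base | previous k bases) as a
    (4**k, 4) array; positions near a sequence start fall back to the longest
    available context.  ``stationary`` is the order-0 base composition.
    """

    order: int
    cond: list[np.ndarray]

    @property
    def stationary(self) -> np.ndarray:
        return self.cond[0][0]

    def window_logprobs(self, enc: np.ndarray, width: int) -> np.ndarray:
        """Natural-log probability of every width-``width`` window, using each
        position's conditional probability given its preceding context (the
        context may extend beyond the window start)."""
        L = enc.size
        logp = np.full(L, np.nan)
        valid = enc >= 0
        safe = np.where(valid, enc, 0)
        # longest-valid-context order per position, vectorised per k
        filled = np.zeros(L, dtype=bool)
        for k in range(self.order, -1, -1):
            if L <= k:
                continue
            pos = np.arange(k, L)
            ok = valid[pos].copy()
            ctx = np.zeros(pos.size, dtype=np.int64)
            for j in range(k, 0, -1):
                ok &= valid[pos - j]
                ctx = ctx * 4 + safe[pos - j]
            sel = ok & valid[pos] & ~filled[pos]
            if sel.any():
                logp[pos[sel]] = np.log(self.cond[k][ctx[sel], enc[pos[sel]]])
                filled[pos[sel]] = True
        if L < width:
            return np.empty(0)
        csum = np.concatenate([[0.0], np.nancumsum(logp)])
        out = csum[width:] - csum[:-width]
        # windows touching an invalid base are NaN
        bad = np.convolve((~valid).astype(int), np.ones(width, dtype=int), "valid") > 0
        out[bad] = np.nan
        return out

    def sample(self, length: int, rng: np.random.Generator) -> str:
        cums = [np.cumsum(c, axis=1) for c in self.cond]
        u = rng.random(length)
        out = np.empty(length, dtype=np.int8)
        ctx = 0
        mod = 4**self.order if self.order else 1
        for i in range(length):
            k = min(self.order, i)
            row = cums[k][ctx % (4**k)]
            b = int(np.searchsorted(row, u[i], side="right"))
            out[i] = min(b, 3)
            ctx = (ctx * 4 + b) % mod
        return decode(out)


def train_background(sequences: list[str], order: int = 3) -> BackgroundModel:
    """Maximum-likelihood Markov background with +1 pseudocount per context
    cell, trained on the given sequences (e.g. all intergenic regions)."""
    if not sequences or not any(sequences):
        raise ValueError("cannot train background on empty input")
    total = sum(len(s) for s in sequences)
    if total <= 4 ** (order + 1):
        warnings.warn(
            f"background training data ({total} bp) is small for order {order}; "
            "transition estimates will be pseudocount-dominated"
        )
    cond = []
    encs = [encode(s) for s in sequences]
    for k in range(order + 1):
        counts = np.ones((4**k, 4))  # +1 pseudocount
        for enc in encs:
            if enc.size <= k:
                continue
            if k:
                ctx = np.zeros(enc.size - k, dtype=np.int64)
                ctx_ok = np.ones(enc.size - k, dtype=bool)
                for j in range(k):
                    part = enc[j : enc.size - k + j]
                    ctx = ctx * 4 + np.where(part >= 0, part, 0)
                    ctx_ok &= part >= 0
                tail = enc[k:]
                sel = ctx_ok & (tail >= 0)
                np.add.at(counts, (ctx[sel], tail[sel]), 1)
            else:
                np.add.at(counts[0], enc[enc >= 0], 1)
        cond.append(counts / counts.sum(axis=1, keepdims=True))
    return BackgroundModel(order=order, cond=cond)


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------


@dataclass
class PSSM:
    """Position-specific scoring matrix over A/C/G/T.

    ``counts`` is a (4, width) matrix of (possibly weighted) site counts;
    ``freqs`` adds ``pseudocount`` per cell and normalises each column to 1.
    """

    motif_id: str
    counts: np.ndarray
    n_sites: float
    pseudocount: float = 0.25
    source: str = "denovo"
    freqs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x width matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        denom = self.counts.sum(axis=0) + 4 * self.pseudocount
        self.freqs = (self.counts + self.pseudocount) / denom

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(DNA[i] for i in self.freqs.argmax(axis=0))

    def revcomp(self) -> "PSSM":
        return PSSM(
            motif_id=self.motif_id + "_rc",
            counts=self.counts[::-1, ::-1].copy(),
            n_sites=self.n_sites,
            pseudocount=self.pseudocount,
            source=self.source,
        )

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        """log2(freq / background) per cell, zero-frequency cells floored."""
        f = np.maximum(self.freqs, _FREQ_FLOOR)
        return np.log2(f / np.asarray(background)[:, None])

    def information_content(self, background: np.ndarray | None = None) -> float:
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        f = np.maximum(self.freqs, _FREQ_FLOOR)
        return float((f * np.log2(f / bg[:, None])).sum())


def build_pssm(
    sites: list[str],
    pseudocount: float = 0.25,
    motif_id: str = "motif",
    source: str = "denovo",
) -> PSSM:
    """Tally a PSSM from equal-length site strings."""
    if not sites:
        raise ValueError("need at least one site")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("sites must have equal widths")
    counts = np.zeros((4, w))
    for s in sites:
        enc = encode(s)
        for j, b in enumerate(enc):
            if b >= 0:
                counts[b, j] += 1
    return PSSM(motif_id=motif_id, counts=counts, n_sites=len(sites), pseudocount=pseudocount, source=source)


# ---------------------------------------------------------------------------
# MEME minimal format I/O
# ---------------------------------------------------------------------------


def write_meme_minimal(pssms: list[PSSM], path: str | Path, background: np.ndarray | None = None) -> None:
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(DNA, bg)) + "\n\n")
        for p in pssms:
            fh.write(f"MOTIF {p.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= {max(int(round(p.n_sites)), 1)} E= 0\n"
            )
            for col in p.freqs.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme_minimal(path: str | Path) -> list[PSSM]:
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        text = fh.read()
    parsed = bio_motifs.parse(io.StringIO(text), "minimal")
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in DNA], dtype=float)
        n_sites = counts.sum(axis=0).max()
        out.append(PSSM(motif_id=m.name, counts=counts, n_sites=float(n_sites), source="reference"))
    return out


# ---------------------------------------------------------------------------
# Scanning with exact p-values
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    genome_id: str
    gene_id: str
    offset: int
    strand: str
    score: float
    p_value: float


class _ScoreDistribution:
    """Exact distribution of the log-odds score of a random width-w word
    under an order-0 background, by dynamic programming over scores rounded
    to the ``SCORE_GRANULARITY`` lattice."""

    def __init__(self, pssm: PSSM, background: np.ndarray):
        lods = pssm.log_odds(background)
        self.s_int = np.rint(lods / SCORE_GRANULARITY).astype(np.int64)
        bg = np.asarray(background, dtype=float)
        cur = np.array([1.0])
        base = 0
        for j in range(pssm.width):
            col = self.s_int[:, j]
            lo, hi = int(col.min()), int(col.max())
            new = np.zeros(cur.size + hi - lo)
            for b in range(4):
                off = int(col[b]) - lo
                new[off : off + cur.size] += cur * bg[b]
            cur = new
            base += lo
        self.base = base
        # survival: P(score >= base + i)
        self.sf = cur[::-1].cumsum()[::-1]

    def score(self, windows: np.ndarray) -> np.ndarray:
        """Integer lattice scores of an (n, w) window matrix."""
        w = windows.shape[1]
        return self.s_int[windows, np.arange(w)].sum(axis=1)

    def pvalue(self, int_scores: np.ndarray) -> np.ndarray:
        idx = np.clip(np.asarray(int_scores) - self.base, 0, self.sf.size - 1)
        out = self.sf[idx]
        out = np.where(np.asarray(int_scores) - self.base >= self.sf.size, 0.0, out)
        return np.minimum(out, 1.0)


def scan_for_hits(pssm: PSSM, igrs: list, bg: BackgroundModel, p_max: float = 1e-4) -> list[MotifHit]:
    """Best hit per IGR per strand with word p-value <= ``p_max``.

    Scores are log2 odds against the order-0 stationary background; p-values
    come from the exact score distribution of a random word.  Windows
    containing N are skipped.  Minus-strand offsets are reported in forward
    coordinates of the IGR (offset of the window's leftmost base).
    """
    dist = _ScoreDistribution(pssm, bg.stationary)
    dist_rc = _ScoreDistribution(pssm.revcomp(), bg.stationary)
    w = pssm.width
    hits: list[MotifHit] = []
    for igr in igrs:
        enc = encode(igr.sequence)
        if enc.size < w:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, w)
        valid = (windows >= 0).all(axis=1)
        if not valid.any():
            continue
        for strand, d in (("+", dist), ("-", dist_rc)):
            scores = np.full(windows.shape[0], np.iinfo(np.int64).min, dtype=np.int64)
            scores[valid] = d.score(windows[valid])
            best = int(scores.argmax())
            if not valid[best]:
                continue
            p = float(d.pvalue(np.array([scores[best]]))[0])
            if p <= p_max:
                hits.append(
                    MotifHit(
                        motif_id=pssm.motif_id,
                        genome_id=igr.genome_id,
                        gene_id=igr.gene_id,
                        offset=best,
                        strand=strand,
                        score=float(scores[best]) * SCORE_GRANULARITY,
                        p_value=p,
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# ZOOPS discovery
# ---------------------------------------------------------------------------


@dataclass
class _WindowSet:
    """All scan windows of a sequence group at one width, both strands."""

    windows: np.ndarray  # (n, w) encoded bases, valid only
    seq_idx: np.ndarray  # (n,) sequence index
    strand: np.ndarray  # (n,) 0 = forward, 1 = reverse
    offset: np.ndarray  # (n,) forward-coordinate offset of window start
    bg_logp: np.ndarray  # (n,) natural-log window probability under bg
    n_seqs: int
    seq_bounds: np.ndarray  # reduceat boundaries per sequence


def _build_windows(encs: list[np.ndarray], width: int, bg: BackgroundModel) -> _WindowSet | None:
    wins, sidx, strands, offs, bgl = [], [], [], [], []
    for i, enc in enumerate(encs):
        if enc.size < width:
            continue
        for strand, e in ((0, enc), (1, revcomp_encoded(enc))):
            wv = np.lib.stride_tricks.sliding_window_view(e, width)
            valid = (wv >= 0).all(axis=1)
            if not valid.any():
                continue
            lp = bg.window_logprobs(e, width)
            pos = np.nonzero(valid)[0]
            wins.append(wv[pos])
            sidx.append(np.full(pos.size, i))
            strands.append(np.full(pos.size, strand))
            fwd_off = pos if strand == 0 else e.size - width - pos
            offs.append(fwd_off)
            bgl.append(lp[pos])
    if not wins:
        return None
    windows = np.concatenate(wins)
    seq_idx = np.concatenate(sidx)
    order = np.argsort(seq_idx, kind="stable")
    windows, seq_idx = windows[order], seq_idx[order]
    strand = np.concatenate(strands)[order]
    offset = np.concatenate(offs)[order]
    bg_logp = np.concatenate(bgl)[order]
    bounds = np.searchsorted(seq_idx, np.unique(seq_idx))
    return _WindowSet(windows, seq_idx, strand, offset, bg_logp, len(encs), bounds)


def _seq_index(seq_of: np.ndarray, uniq: np.ndarray) -> np.ndarray:
    return np.searchsorted(uniq, seq_of)


def _pick_seeds(
    encs: list[np.ndarray],
    ws: _WindowSet,
    width: int,
    n_seeds: int,
    rng: np.random.Generator,
    kmer: int = 8,
) -> np.ndarray:
    """Choose EM seed windows: half by a repeated-word screen (windows
    containing the k-mers that recur most often across the group, the
    hallmark of a shared motif), half uniformly at random."""
    n_win = ws.windows.shape[0]
    k = min(kmer, width)
    counts: dict[int, int] = {}
    weights = 4 ** np.arange(k - 1, -1, -1)
    for enc in encs:
        for e in (enc, revcomp_encoded(enc)):
            if e.size < k:
                continue
            wv = np.lib.stride_tricks.sliding_window_view(e, k)
            valid = (wv >= 0).all(axis=1)
            codes = wv[valid] @ weights
            for c, n in zip(*np.unique(codes, return_counts=True)):
                counts[int(c)] = counts.get(int(c), 0) + int(n)
    wv = np.lib.stride_tricks.sliding_window_view(ws.windows, (1, k)).reshape(
        n_win, width - k + 1, k
    )
    codes = wv @ weights  # (n_win, width-k+1)
    score = np.empty(n_win)
    lookup = np.vectorize(lambda c: counts.get(int(c), 0))
    score = lookup(codes).max(axis=1)
    n_top = min(n_seeds // 2 + n_seeds % 2, n_win)
    jitter = rng.random(n_win)
    order = np.lexsort((jitter, -score))
    top = order[:n_top]
    rest = rng.choice(n_win, size=min(n_seeds - n_top, n_win), replace=False)
    return np.unique(np.concatenate([top, rest]))


def _best_llr(
    encs: list[np.ndarray],
    width: int,
    bg: BackgroundModel,
    rng: np.random.Generator,
    n_seeds: int,
    n_iter_seed: int,
    n_iter_refine: int,
    n_finalists: int = 2,
):
    """Seed-search + refine ZOOPS fit at one width.  Returns
    (llr, theta, pi, window-set) or None if no valid windows."""
    ws = _build_windows(encs, width, bg)
    if ws is None or ws.windows.shape[0] < 2:
        return None
    n_win = ws.windows.shape[0]
    n_seeds = min(n_seeds, n_win)
    seed_idx = _pick_seeds(encs, ws, width, n_seeds, rng)
    theta0 = np.full((len(seed_idx), 4, width), 0.1)
    for k, si in enumerate(seed_idx):
        theta0[k, ws.windows[si], np.arange(width)] = 0.7
    thetas, _, llrs = _zoops_em_multi(ws, theta0, n_iter_seed)
    order = np.argsort(llrs)[::-1][:n_finalists]
    best = None
    for k in order:
        th, pi, llr = _zoops_em_multi(ws, thetas[k][None], n_iter_refine)
        th, pi, llr = th[0], float(pi[0]), float(llr[0])
        if best is None or llr > best[0]:
            best = (llr, th, pi)
    llr, th, pi = best
    return llr, th, pi, ws


def _zoops_em_multi(ws: _WindowSet, theta0: np.ndarray, n_iter: int):
    """Run batched EM keeping all models; returns (thetas, pis, llrs)."""
    m, _, w = theta0.shape
    theta = theta0.copy()
    pi = np.full(m, 0.5)
    win = ws.windows
    uniq = np.unique(ws.seq_idx)
    n_per_seq = np.bincount(ws.seq_idx)[uniq].astype(float)
    cols = np.arange(w)
    sidx = _seq_index(ws.seq_idx, uniq)
    llrs = np.zeros(m)
    for _ in range(n_iter):
        logtheta = np.log(np.maximum(theta, 1e-12))
        lw = logtheta[:, win, cols].sum(axis=2)
        r = np.exp(np.clip(lw - ws.bg_logp[None, :], -700, 700))
        sum_r = np.empty((m, uniq.size))
        for k in range(m):
            sum_r[k] = np.add.reduceat(r[k], ws.seq_bounds)
        prior = pi[:, None] / n_per_seq[None, :]
        denom = (1 - pi)[:, None] + prior * sum_r
        llrs = np.log(denom).sum(axis=1)
        resp = prior[:, sidx] * r / denom[:, sidx]
        new_theta = np.full((m, 4, w), 0.125)
        for b in range(4):
            new_theta[:, b, :] += resp @ (win == b)
        theta = new_theta / new_theta.sum(axis=1, keepdims=True)
        pi = np.clip((prior * sum_r / denom).mean(axis=1), 1e-3, 1 - 1e-3)
    return theta, pi, llrs


@dataclass
class NullCalibration:
    """Calibration of the null max-LLR distribution of ZOOPS discovery.

    For each width, stores null draws (log total window count, max LLR) from
    discovery runs on background-resampled sequence groups; predicts the
    null mean by linear regression on log window count, with the residual
    standard deviation as spread.
    """

    draws: dict[int, list[tuple[float, float]]] = field(default_factory=dict)

    def add(self, width: int, n_windows: int, llr: float) -> None:
        self.draws.setdefault(width, []).append((float(np.log(max(n_windows, 2))), llr))

    def pvalue(self, width: int, n_windows: int, llr: float) -> float:
        pts = self.draws.get(width)
        if not pts or len(pts) < 4:
            raise ValueError(f"no calibration for width {width}")
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        if np.ptp(x) < 1e-9:
            mu = y.mean()
            resid = y - mu
            dof = len(y) - 1
        else:
            slope, intercept = np.polyfit(x, y, 1)
            mu = slope * np.log(max(n_windows, 2)) + intercept
            resid = y - (slope * x + intercept)
            dof = len(y) - 2
        sd = float(np.sqrt((resid**2).sum() / dof))
        sd = max(sd, 1e-6)
        t = (llr - mu) / (sd * np.sqrt(1 + 1.0 / len(y)))
        return float(stats.t.sf(t, df=dof))


def calibrate_null(
    bg: BackgroundModel,
    widths: tuple[int, ...],
    length_profiles: list[list[int]],
    seed: int = 0,
    n_seeds: int = 16,
    n_iter_seed: int = 3,
    n_iter_refine: int = 20,
) -> NullCalibration:
    """Fit a :class:`NullCalibration` by running discovery on groups of
    background-sampled sequences with the given length profiles."""
    rng = np.random.default_rng(seed)
    calib = NullCalibration()
    for lengths in length_profiles:
        seqs = [encode(bg.sample(L, rng)) for L in lengths]
        for w in widths:
            res = _best_llr(seqs, w, bg, rng, n_seeds, n_iter_seed, n_iter_refine)
            if res is None:
                continue
            llr, _, _, ws = res
            calib.add(w, ws.windows.shape[0], llr)
    return calib


@dataclass
class DiscoveredMotif:
    pssm: PSSM
    sites: list[tuple[int, str, int]]  # (seq index, strand, forward offset)
    evalue: float
    llr: float


def discover_motifs_zoops(
    seq_group: list[str],
    bg: BackgroundModel,
    nmotifs: int = 3,
    max_width: int = 30,
    evalue_max: float = 0.01,
    widths: tuple[int, ...] | None = None,
    seed: int = 0,
    n_null: int = 8,
    calibration: NullCalibration | None = None,
    n_seeds: int = 16,
    n_iter_seed: int = 3,
    n_iter_refine: int = 20,
    motif_prefix: str = "motif",
) -> list[DiscoveredMotif]:
    """De novo ZOOPS motif discovery on a group of sequences (both strands).

    Up to ``nmotifs`` motifs are returned; each discovered motif's sites are
    masked before the next search, and search stops at the first motif whose
    significance exceeds ``evalue_max``.  Significance is the upper-tail
    probability of the observed maximum EM log-likelihood ratio under a null
    of sequences resampled from ``bg`` — estimated per group (``n_null``
    replicate groups) or from a precomputed :class:`NullCalibration`.
    """
    if widths is None:
        widths = tuple(w for w in (8, 12, 16) if w <= max_width) or (max_width,)
    rng = np.random.default_rng(seed)
    encs = [encode(s) for s in seq_group]
    found: list[DiscoveredMotif] = []
    for round_no in range(nmotifs):
        best = None
        for w in widths:
            res = _best_llr(encs, w, bg, rng, n_seeds, n_iter_seed, n_iter_refine)
            if res is None:
                continue
            llr, theta, pi, ws = res
            if calibration is not None:
                p = calibration.pvalue(w, ws.windows.shape[0], llr)
            else:
                null_llrs = []
                lengths = [e.size for e in encs]
                for _ in range(n_null):
                    null_encs = [encode(bg.sample(L, rng)) for L in lengths]
                    nres = _best_llr(null_encs, w, bg, rng, n_seeds, n_iter_seed, n_iter_refine)
                    if nres is not None:
                        null_llrs.append(nres[0])
                if len(null_llrs) < 3:
                    continue
                mu, sd = float(np.mean(null_llrs)), float(np.std(null_llrs, ddof=1))
                sd = max(sd, 1e-6)
                t = (llr - mu) / (sd * np.sqrt(1 + 1.0 / len(null_llrs)))
                p = float(stats.t.sf(t, df=len(null_llrs) - 1))
            if best is None or p < best[0] or (p == best[0] and llr > best[1]):
                best = (p, llr, w, theta, pi, ws)
        if best is None or best[0] > evalue_max:
            break
        p, llr, w, theta, pi, ws = best
        # extract hard sites: best-responsibility window per sequence with site prob > 0.5
        logtheta = np.log(np.maximum(theta, 1e-12))
        lw = logtheta[ws.windows, np.arange(w)].sum(axis=1)
        r = np.exp(np.clip(lw - ws.bg_logp, -700, 700))
        sites: list[tuple[int, str, int]] = []
        site_strings: list[str] = []
        uniq = np.unique(ws.seq_idx)
        for s in uniq:
            sel = np.nonzero(ws.seq_idx == s)[0]
            sum_r = r[sel].sum()
            n_s = sel.size
            p_site = (pi / n_s) * sum_r / ((1 - pi) + (pi / n_s) * sum_r)
            if p_site <= 0.5:
                continue
            k = sel[int(r[sel].argmax())]
            strand = "+" if ws.strand[k] == 0 else "-"
            sites.append((int(s), strand, int(ws.offset[k])))
            site_strings.append(decode(ws.windows[k]))
        if len(sites) < 2:
            break
        pssm = build_pssm(site_strings, motif_id=f"{motif_prefix}_{round_no + 1}", source="denovo")
        found.append(DiscoveredMotif(pssm=pssm, sites=sites, evalue=p, llr=llr))
        # mask sites before next round
        for s, strand, off in sites:
            encs[s][off : off + w] = -1
    return found


# ---------------------------------------------------------------------------
# PSSM comparison and clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifComparison:
    offset: int
    orientation: str  # "forward" | "reverse"
    statistic: float
    p_value: float


def _column_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(wa, wb) matrix of Pearson correlations between frequency columns."""
    za = a - a.mean(axis=0, keepdims=True)
    zb = b - b.mean(axis=0, keepdims=True)
    na = np.sqrt((za**2).sum(axis=0))
    nb = np.sqrt((zb**2).sum(axis=0))
    na[na == 0] = np.inf
    nb[nb == 0] = np.inf
    return (za / na).T @ (zb / nb)


def _overlap_stats(C: np.ndarray, min_cols: int) -> list[tuple[float, int, np.ndarray, np.ndarray]]:
    """All ungapped alignments with >= min_cols overlapping columns.
    Returns (statistic, offset, a-col indices, b-col indices)."""
    wa, wb = C.shape
    out = []
    for off in range(-(wb - min_cols), wa - min_cols + 1):
        ai = np.arange(max(0, off), min(wa, wb + off))
        bi = ai - off
        if ai.size < min_cols:
            continue
        out.append((float(C[ai, bi].mean()), off, ai, bi))
    return out


def compare_pssms(
    a: PSSM,
    b: PSSM,
    n_shuffle: int = 1000,
    seed: int = 0,
    min_overlap_cols: int = 4,
) -> MotifComparison:
    """Compare two PSSMs by per-column Pearson correlation of frequency
    columns over the best ungapped overlap (>= 4 columns), across both
    orientations of ``b``.

    The alignment (and the null) is scored by the SUM of column
    correlations, so longer consistent overlaps dominate chance short ones;
    the reported statistic is the mean correlation at that alignment.  The
    p-value compares the observed alignment score against the maximised
    score of column-shuffled versions of ``b``, with a Gumbel tail fit for
    observations beyond the shuffle range."""
    fa, fb = a.freqs, b.freqs
    fb_rc = b.revcomp().freqs
    C_f = _column_corr(fa, fb)
    C_r = _column_corr(fa, fb_rc)
    obs = None
    for orient, C in (("forward", C_f), ("reverse", C_r)):
        for mean_stat, off, ai, bi in _overlap_stats(C, min_overlap_cols):
            total = mean_stat * ai.size
            if obs is None or total > obs[0]:
                obs = (total, mean_stat, off, orient)
    if obs is None:
        return MotifComparison(offset=0, orientation="forward", statistic=-1.0, p_value=1.0)
    sum_obs, stat_obs, off_obs, orient_obs = obs
    # null: column permutations of b
    rng = np.random.default_rng(seed)
    wb = fb.shape[1]
    perms = np.array([rng.permutation(wb) for _ in range(n_shuffle)])
    # corr of a-columns with complemented b-columns (for reverse orientation of shuffled b)
    C_comp = _column_corr(fa, fb[::-1, :])
    null_max = np.full(n_shuffle, -np.inf)
    # forward orientation of shuffled b: score over offsets using C_f with permuted b columns
    for _, off, ai, bi in _overlap_stats(C_f, min_overlap_cols):
        idx = perms[:, bi]  # (n_shuffle, k) permuted b columns
        vals = C_f[ai[None, :], idx].sum(axis=1)
        np.maximum(null_max, vals, out=null_max)
    # reverse orientation: column j of revcomp(shuffled b) = complement of shuffled-b column (wb-1-j)
    for _, off, ai, bi in _overlap_stats(C_comp, min_overlap_cols):
        idx = perms[:, wb - 1 - bi]
        vals = C_comp[ai[None, :], idx].sum(axis=1)
        np.maximum(null_max, vals, out=null_max)
    count = int((null_max >= sum_obs - 1e-12).sum())
    p = (1.0 + count) / (n_shuffle + 1.0)
    if count < 10:
        # smooth the extreme tail with a Gumbel fit to the null maxima
        # (method of moments); the empirical floor 1/(n+1) is otherwise the
        # smallest attainable p and washes out after multiple-testing control
        mu_n, sd_n = float(null_max.mean()), float(null_max.std(ddof=1))
        if sd_n > 0:
            beta = sd_n * np.sqrt(6.0) / np.pi
            mu_g = mu_n - 0.5772156649 * beta
            z = (sum_obs - mu_g) / beta
            p_tail = float(-np.expm1(-np.exp(-z)))
            p = min(p, max(p_tail, 1e-300))
    return MotifComparison(offset=off_obs, orientation=orient_obs, statistic=stat_obs, p_value=p)


def qvalues(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def hit_key(hit: MotifHit, width: int, bin_size: int = 5) -> tuple[str, int]:
    """Identity of a hit for overlap computation: gene and the bin of the
    hit window's midpoint.  Strand is ignored and the midpoint used so that
    motif variants of different widths or opposite orientations discovered
    at the same genomic site are recognised as the same instance."""
    return (hit.gene_id, (hit.offset + width // 2) // bin_size)


def _matched(a: set, b: set) -> int:
    by_gene: dict[str, set[int]] = {}
    for gene, bin_ in b:
        by_gene.setdefault(gene, set()).add(bin_)
    n = 0
    for gene, bin_ in a:
        bins = by_gene.get(gene)
        if bins and (bin_ in bins or bin_ - 1 in bins or bin_ + 1 in bins):
            n += 1
    return n


def overlap_coefficient(a: set, b: set) -> float:
    """Fraction of the smaller hit set matched in the other (same gene,
    midpoint bins within +-1)."""
    if not a or not b:
        return 0.0
    return max(_matched(a, b), _matched(b, a)) / min(len(a), len(b))


@dataclass
class MotifFamilyCluster:
    cluster_id: str
    members: list[str]
    hit_union: set = field(default_factory=set)
    species_pssms: dict[str, PSSM] = field(default_factory=dict)


def cluster_motifs(
    motifs: list[PSSM],
    hits: dict[str, set],
    pair_q: dict[frozenset, float],
    q_max: float = 0.01,
    min_overlap: float = 0.33,
) -> list[MotifFamilyCluster]:
    """Single-linkage clustering of motifs whose target-genome hit sets
    overlap by at least ``min_overlap`` (overlap coefficient) AND whose
    pairwise comparison q-value is below ``q_max``.  Motifs with no
    qualifying partner form singletons."""
    import networkx as nx

    ids = sorted(p.motif_id for p in motifs)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, mi in enumerate(ids):
        for mj in ids[i + 1 :]:
            q = pair_q.get(frozenset((mi, mj)))
            if q is None or q >= q_max:
                continue
            if overlap_coefficient(hits.get(mi, set()), hits.get(mj, set())) >= min_overlap:
                g.add_edge(mi, mj)
    clusters = []
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for k, comp in enumerate(comps):
        members = sorted(comp)
        union: set = set()
        for m in members:
            union |= hits.get(m, set())
        clusters.append(MotifFamilyCluster(cluster_id=f"MC{k:03d}", members=members, hit_union=union))
    return clusters
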