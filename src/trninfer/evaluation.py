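"""Evaluation of predicted TF-target interactions against a gold standard:
precision, gold-restricted precision, recall, precision-recall curves at
fixed prediction intervals, AUPR, and per-TF report tables.

Report conventions: a TF with no predictions is NA; a TF whose predictions
are all wrong is 0; column averages are arithmetic means over non-NA
entries (zeros included).  Percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class GoldStandard:
    interactions: set[tuple[str, str]]
    tfs_with_data: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.tfs_with_data:
            self.tfs_with_data = {tf for tf, _ in self.interactions}
        missing = {tf for tf, _ in self.interactions} - self.tfs_with_data
        if missing:
            raise ValueError(f"gold interactions for TFs without data: {sorted(missing)}")


def read_gold(path: str | Path, assayed_path: str | Path | None = None) -> GoldStandard:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    interactions = set(zip(df["tf"], df["target"]))
    tfs = set()
    if assayed_path is not None:
        tfs = set(pd.read_csv(assayed_path, sep="\t", dtype=str).iloc[:, 0])
    return GoldStandard(interactions=interactions, tfs_with_data=tfs or set())


def write_gold(gold: GoldStandard, path: str | Path, assayed_path: str | Path | None = None) -> None:
    pd.DataFrame(sorted(gold.interactions), columns=["tf", "target"]).to_csv(path, sep="\t", index=False)
    if assayed_path is not None:
        pd.DataFrame(sorted(gold.tfs_with_data), columns=["tf"]).to_csv(assayed_path, sep="\t", index=False)


def precision(preds: set[tuple[str, str]], gold: GoldStandard) -> float | None:
    """True positives over all predictions; None (NA) for empty input."""
    if not preds:
        return None
    return len(preds & gold.interactions) / len(preds)


def restricted_precision(preds: set[tuple[str, str]], gold: GoldStandard) -> float | None:
    """Precision over only those predictions whose TF has gold data."""
    kept = {p for p in preds if p[0] in gold.tfs_with_data}
    if not kept:
        return None
    return len(kept & gold.interactions) / len(kept)


def recall(preds: set[tuple[str, str]], gold: GoldStandard) -> float:
    """True positives over all known true positives."""
    if not gold.interactions:
        raise ValueError("empty gold standard")
    return len(preds & gold.interactions) / len(gold.interactions)


@dataclass(frozen=True)
class PRPoint:
    n_predictions: int
    precision: float
    recall: float


def pr_curve(
    ranked_preds: list[tuple[str, str]],
    gold: GoldStandard,
    interval: int = 100,
    restricted: bool = False,
) -> list[PRPoint]:
    """Precision and recall at prefix sizes interval, 2*interval, ...; the
    final partial prefix is always included."""
    n = len(ranked_preds)
    sizes = list(range(interval, n + 1, interval))
    if not sizes or sizes[-1] != n:
        sizes.append(n)
    prec_fn = restricted_precision if restricted else precision
    points = []
    for k in sizes:
        prefix = set(ranked_preds[:k])
        p = prec_fn(prefix, gold)
        points.append(PRPoint(n_predictions=k, precision=0.0 if p is None else p, recall=recall(prefix, gold)))
    return points


def aupr(curve: list[PRPoint]) -> float:
    """Trapezoidal area over the recall axis, anchored at recall 0 with the
    first point's precision."""
    if len(curve) < 2:
        raise ValueError("need at least 2 PR points")
    rec = np.array([0.0] + [p.recall for p in curve])
    prec = np.array([curve[0].precision] + [p.precision for p in curve])
    return float(np.trapezoid(prec, rec))


def _round1(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def per_tf_report(preds: set[tuple[str, str]], gold: GoldStandard) -> pd.DataFrame:
    """Per-gold-TF precision% and recall% (1 decimal), NA when the TF has no
    predictions, with a bottom Average row over non-NA entries."""
    rows = []
    for tf in sorted(gold.tfs_with_data):
        tf_preds = {p for p in preds if p[0] == tf}
        tf_gold = GoldStandard(
            interactions={g for g in gold.interactions if g[0] == tf},
            tfs_with_data={tf},
        )
        if not tf_preds:
            rows.append({"tf": tf, "precision_pct": np.nan, "recall_pct": np.nan})
            continue
        p = precision(tf_preds, tf_gold)
        r = recall(tf_preds, tf_gold) if tf_gold.interactions else 0.0
        rows.append({"tf": tf, "precision_pct": _round1(100 * p), "recall_pct": _round1(100 * r)})
    df = pd.DataFrame(rows)
    avg = {
        "tf": "Average",
        "precision_pct": _round1(float(df["precision_pct"].dropna().mean())) if df["precision_pct"].notna().any() else np.nan,
        "recall_pct": _round1(float(df["recall_pct"].dropna().mean())) if df["recall_pct"].notna().any() else np.nan,
    }
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


def column_average(values: pd.Series) -> float:
    """The report averaging convention applied to a printed column: NA
    entries are excluded, zeros included, result rounded half-up to one
    decimal."""
    vals = pd.to_numeric(values, errors="coerce").dropna()
    return _round1(float(vals.mean()))


def load_tf_benchmark() -> pd.DataFrame:
    """Published per-TF precision/recall benchmark for E. coli network
    inference (integrated, CLR, and tree-ensemble approaches), with NA
    marking TFs for which an approach made no predictions.  Used as a
    regression fixture for the report-averaging conventions."""
    with resources.files("trninfer.data").joinpath("ecoli_tf_benchmark.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
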