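"""Confusion-matrix accounting and TPR/PPV/F1 on the 0–100 scale.

Metrics are evaluated only over samples with known ground truth (for the
ovarian-cancer exome benchmarks, the variants confirmed or rejected by
high-depth targeted resequencing).  TPR = TP/(TP+FN), PPV = TP/(TP+FP),
F1 = 2·TPR·PPV/(TPR+PPV); all reported as percentages rounded half-up to
two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(calls: dict[str, bool], truth: dict[str, bool]) -> ConfusionCounts:
    """Tally calls against ground truth, over the truth ids only.

    Samples present in ``truth`` but absent from ``calls`` count as
    negative calls (the method did not call them).
    """
    if not truth:
        raise ValueError("empty ground truth")
    tp = fp = tn = fn = 0
    for sid, is_true in truth.items():
        called = bool(calls.get(sid, False))
        if called and is_true:
            tp += 1
        elif called and not is_true:
            fp += 1
        elif not called and is_true:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def tpr(c: ConfusionCounts, rounded: bool = True) -> float | None:
    """True positive rate (sensitivity) as a percentage; None if TP+FN = 0."""
    if c.tp + c.fn == 0:
        return None
    v = 100.0 * c.tp / (c.tp + c.fn)
    return _round2(v) if rounded else v


def ppv(c: ConfusionCounts, rounded: bool = True) -> float | None:
    """Positive predictive value (precision) as a percentage; None if TP+FP = 0."""
    if c.tp + c.fp == 0:
        return None
    v = 100.0 * c.tp / (c.tp + c.fp)
    return _round2(v) if rounded else v


def f1(c: ConfusionCounts, rounded: bool = True) -> float | None:
    """F1 — the harmonic mean of TPR and PPV — as a percentage."""
    t = tpr(c, rounded=False)
    p = ppv(c, rounded=False)
    if t is None or p is None or t + p == 0:
        return None
    v = 2.0 * t * p / (t + p)
    return _round2(v) if rounded else v


def expected_tp(n_calls: int, ppv_percent: float) -> int:
    """Expected confirmed positives when resequencing ``n_calls`` candidates
    under a constant-PPV assumption."""
    return int(round(n_calls * ppv_percent / 100.0))


def evaluation_report(rows: list[dict]) -> pd.DataFrame:
    """Tab-friendly report: one row per (dataset, caller) with counts and
    the three metrics.  Each input dict needs dataset, caller and a
    ConfusionCounts under key ``counts``."""
    out = []
    for row in rows:
        c: ConfusionCounts = row["counts"]
        out.append({
            "dataset": row.get("dataset", ""),
            "caller": row.get("caller", ""),
            "n_calls": row.get("n_calls", ""),
            "TP": c.tp, "FP": c.fp, "TN": c.tn, "FN": c.fn,
            "TPR": tpr(c), "PPV": ppv(c), "F1": f1(c),
        })
    return pd.DataFrame(out)


def load_ovarian_benchmark() -> pd.DataFrame:
    """Published per-caller confusion counts on four ovarian-cancer exome
    datasets (columns: dataset, caller, n_calls, tp, fp, tn, fn, and the
    printed tpr/ppv/f1 percentages)."""
    with resources.files("plato.data").joinpath("ovarian_benchmark.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
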