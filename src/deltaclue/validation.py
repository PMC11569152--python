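"""Quantitative map validation.

Agreement between a predicted and a reference categorical map is
summarised by a confusion matrix (rows = predicted class, columns =
reference class), overall accuracy, per-class user's accuracy (correct /
row total) and producer's accuracy (correct / column total), overall
accuracy after majority aggregation to coarser grids (to discount
near-misses), and the same metric set for a no-change null model — the
old map used as a predictor of the new one.  Percentages are reported to
one decimal, rounded half away from zero, matching the study tables.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .grid import CategoricalRaster, check_aligned
from .prep import majority_aggregate
from .suitability import UndefinedMetricError

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "overall_accuracy",
    "class_accuracies",
    "multiresolution_accuracy",
    "null_model_report",
    "round1",
]


def round1(x: float) -> float:
    """Round to one decimal, half away from zero."""
    return math.copysign(math.floor(abs(x) * 10 + 0.5) / 10, x)


@dataclasses.dataclass
class ConfusionMatrix:
    """Cross-tabulation of predicted (rows) vs reference (columns) classes."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.counts.index) != list(self.counts.columns):
            raise ValueError("row and column class sets must match")

    @property
    def class_codes(self) -> list:
        return list(self.counts.index)

    @property
    def grand_total(self) -> int:
        return int(self.counts.values.sum())


def confusion_matrix(
    pred: CategoricalRaster,
    ref: CategoricalRaster,
    mask: np.ndarray | None = None,
    class_codes: Sequence[int] | None = None,
) -> ConfusionMatrix:
    """Count active cells per (predicted, reference) class pair."""
    check_aligned(pred, ref)
    ok = pred.data_mask & ref.data_mask
    if mask is not None:
        ok &= mask
    p = pred.values[ok]
    r = ref.values[ok]
    present = sorted({int(v) for v in np.unique(p)} | {int(v) for v in np.unique(r)})
    if class_codes is None:
        codes = present
    else:
        codes = sorted(int(c) for c in class_codes)
        stray = [c for c in present if c not in codes]
        if stray:
            raise ValueError(f"classes {stray} present in maps but not in class_codes")
    k = len(codes)
    counts = np.zeros((k, k), dtype=np.int64)
    if p.size:
        lookup = np.full(max(codes) + 1, -1, dtype=np.int64)
        lookup[codes] = np.arange(k)
        np.add.at(counts, (lookup[p], lookup[r]), 1)
    frame = pd.DataFrame(counts, index=pd.Index(codes, name="predicted"),
                         columns=pd.Index(codes, name="reference"))
    return ConfusionMatrix(frame)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percent of cells on the diagonal, to one decimal."""
    total = cm.grand_total
    if total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    return round1(100.0 * float(np.trace(cm.counts.values)) / total)


def class_accuracies(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class user's and producer's accuracy (%, one decimal).

    User's accuracy divides the diagonal by the row (prediction) total,
    producer's by the column (reference) total; a zero total leaves the
    metric undefined (NaN) for that class.
    """
    c = cm.counts.values.astype(float)
    diag = np.diag(c)
    rows = c.sum(axis=1)
    cols = c.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        user = np.where(rows > 0, 100.0 * diag / np.maximum(rows, 1), np.nan)
        producer = np.where(cols > 0, 100.0 * diag / np.maximum(cols, 1), np.nan)
    out = pd.DataFrame(
        {
            "users_pct": [round1(v) if np.isfinite(v) else np.nan for v in user],
            "producers_pct": [round1(v) if np.isfinite(v) else np.nan for v in producer],
        },
        index=cm.counts.index.rename("class"),
    )
    return out


def multiresolution_accuracy(
    pred: CategoricalRaster,
    ref: CategoricalRaster,
    factors: Sequence[int],
    pad: bool = True,
) -> pd.DataFrame:
    """Overall accuracy after majority-aggregating both maps per factor."""
    check_aligned(pred, ref)
    rows = []
    for factor in factors:
        if factor < 1:
            raise ValueError("factors must be >= 1")
        if factor > min(pred.spec.nrows, pred.spec.ncols):
            raise ValueError(f"factor {factor} exceeds the grid size")
        if factor == 1:
            cp, cr = pred, ref
        else:
            cp, _ = majority_aggregate(pred, factor, pad=pad)
            cr, _ = majority_aggregate(ref, factor, pad=pad)
        acc = overall_accuracy(confusion_matrix(cp, cr))
        rows.append({"factor": int(factor), "overall_accuracy_pct": acc})
    return pd.DataFrame(rows)


def null_model_report(
    baseline_map: CategoricalRaster,
    ref: CategoricalRaster,
    mask: np.ndarray | None = None,
) -> dict:
    """The no-change null model: the old map as predictor of the new one."""
    cm = confusion_matrix(baseline_map, ref, mask=mask)
    return {
        "label": "null",
        "confusion": cm,
        "overall_accuracy_pct": overall_accuracy(cm),
        "class_accuracies": class_accuracies(cm),
    }
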