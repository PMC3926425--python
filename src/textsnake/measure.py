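"""Overlap, area and classification metrics.

The segmentation accuracy measure is the Jaccard overlap
omega = |a1 ∩ a2| / |a1 ∪ a2| between two pixel masks.  Areas are
reported in pixels and, given a microns-per-pixel calibration, in um^2.
Classifier quality is summarized by a confusion matrix (rows =
predicted, columns = true) with per-class precision/recall and overall
accuracy in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import Calibration

__all__ = [
    "ConfusionMatrix",
    "jaccard",
    "area",
    "compare_areas",
    "confusion_metrics",
]

#: marker for metrics that are undefined (0/0) for a given input
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows are predicted classes, columns true."""

    counts: np.ndarray
    class_names: tuple

    def __post_init__(self):
        m = np.asarray(self.counts, dtype=np.int64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("confusion matrix must be square")
        if len(self.class_names) != m.shape[0]:
            raise ValueError("one class name per row required")
        if (m < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", m)
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @classmethod
    def from_labels(cls, predicted, true, class_names=None) -> "ConfusionMatrix":
        predicted = list(predicted)
        true = list(true)
        if class_names is None:
            class_names = sorted(set(predicted) | set(true))
        index = {n: i for i, n in enumerate(class_names)}
        m = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
        for p, t in zip(predicted, true):
            m[index[p], index[t]] += 1
        return cls(counts=m, class_names=tuple(class_names))


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap omega = |a ∩ b| / |a ∪ b| in [0, 1].

    Two empty masks are identical shapes, so omega is defined as 1.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def area(mask: np.ndarray, cal: Calibration | float | None = None) -> tuple:
    """Mask area as (pixel count, physical area in um^2 or None)."""
    px = int(np.asarray(mask, dtype=bool).sum())
    if cal is None:
        return px, None
    mpp = cal.microns_per_pixel if isinstance(cal, Calibration) else float(cal)
    if not mpp > 0:
        raise ValueError("calibration must be > 0")
    return px, px * mpp * mpp


def compare_areas(a: np.ndarray, b: np.ndarray, cal: Calibration | float = 1.0) -> tuple:
    """(area(a) - area(b), area(a)/area(b)) in physical units.

    The ratio is NaN (undefined marker) when b is empty.
    """
    _, pa = area(a, cal)
    _, pb = area(b, cal)
    diff = pa - pb
    ratio = pa / pb if pb > 0 else UNDEFINED
    return diff, ratio


def confusion_metrics(cm: ConfusionMatrix) -> dict:
    """Per-class precision/recall and overall accuracy, in percent.

    precision_k = 100 * cm[k,k] / row_k  (predicted-k that are truly k)
    recall_k    = 100 * cm[k,k] / col_k  (true-k that are predicted k)
    accuracy    = 100 * trace / total

    A zero row or column yields the NaN undefined marker for that metric.
    """
    m = cm.counts.astype(float)
    total = m.sum()
    if total == 0:
        raise ValueError("all-zero confusion matrix")
    diag = np.diag(m)
    rows = m.sum(axis=1)
    cols = m.sum(axis=0)
    precision = {
        name: (100.0 * diag[i] / rows[i] if rows[i] > 0 else UNDEFINED)
        for i, name in enumerate(cm.class_names)
    }
    recall = {
        name: (100.0 * diag[i] / cols[i] if cols[i] > 0 else UNDEFINED)
        for i, name in enumerate(cm.class_names)
    }
    return {
        "precision": precision,
        "recall": recall,
        "accuracy": 100.0 * diag.sum() / total,
    }


def is_undefined(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)
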