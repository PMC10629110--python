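"""Segmentation and classification metrics.

Segmentation is scored per slice: Dice overlap, 95th-percentile symmetric
Hausdorff distance between mask boundaries (physical units via pixel
spacing), and pixel-level precision/recall.  Classification is scored per
patient with mutant as the positive class: accuracy, precision, recall
and F1 (harmonic mean of precision and recall).

Conventions for degenerate inputs (documented, exercised in tests):

* both masks empty -> Dice 1.0, HD95 0.0;
* exactly one mask empty -> HD95 returns the image diagonal in mm as a
  sentinel (flagged via ``hd95_flagged``);
* empty denominators in precision/recall -> 1.0 when the reference set is
  also empty, else 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "dice_score",
    "boundary_pixels",
    "surface_distances",
    "hd95",
    "hd95_flagged",
    "pixel_precision_recall",
    "classification_report",
]

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def _check_pair(pred, true):
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    return pred.astype(bool), true.astype(bool)


def confusion_counts(pred, true) -> ConfusionCounts:
    pred, true = _check_pair(pred, true)
    return ConfusionCounts(
        tp=int(np.sum(pred & true)),
        fp=int(np.sum(pred & ~true)),
        fn=int(np.sum(~pred & true)),
        tn=int(np.sum(~pred & ~true)),
    )


def dice_score(pred, true) -> float:
    """2 TP / (2 TP + FN + FP); 1.0 when both masks are empty."""
    c = confusion_counts(pred, true)
    denom = 2 * c.tp + c.fn + c.fp
    return 1.0 if denom == 0 else 2.0 * c.tp / denom


def boundary_pixels(mask) -> np.ndarray:
    """(k, 2) row/col coordinates of foreground pixels with a background
    4-neighbor (image border counts as background)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.empty((0, 2), dtype=int)
    interior = ndimage.binary_erosion(mask, structure=_FOUR_CONNECTED,
                                      border_value=0)
    return np.argwhere(mask & ~interior)


def surface_distances(pred, true, spacing=(1.0, 1.0)):
    """Directed boundary distance sets (pred->true, true->pred) in mm."""
    pred, true = _check_pair(pred, true)
    bp = boundary_pixels(pred) * np.asarray(spacing)
    bt = boundary_pixels(true) * np.asarray(spacing)
    if len(bp) == 0 or len(bt) == 0:
        raise ValueError("surface distances need two non-empty masks")
    d_pred = cKDTree(bt).query(bp)[0]
    d_true = cKDTree(bp).query(bt)[0]
    return d_pred, d_true


def hd95_flagged(pred, true, spacing=(1.0, 1.0)) -> tuple[float, bool]:
    """(hd95_mm, degenerate) — degenerate marks the one-side-empty sentinel."""
    pred, true = _check_pair(pred, true)
    if not pred.any() and not true.any():
        return 0.0, False
    if not pred.any() or not true.any():
        diag = float(np.hypot(pred.shape[0] * spacing[0], pred.shape[1] * spacing[1]))
        return diag, True
    d_pred, d_true = surface_distances(pred, true, spacing)
    # linear-interpolation percentile of each directed set, then symmetrize
    value = max(np.percentile(d_pred, 95), np.percentile(d_true, 95))
    return float(value), False


def hd95(pred, true, spacing=(1.0, 1.0)) -> float:
    """Symmetric 95th-percentile Hausdorff distance in mm."""
    return hd95_flagged(pred, true, spacing)[0]


def _safe_ratio(num: int, denom: int, reference_empty: bool) -> float:
    if denom == 0:
        return 1.0 if reference_empty else 0.0
    return num / denom


def pixel_precision_recall(pred, true) -> tuple[float, float]:
    """(TP/(TP+FP), TP/(TP+FN)) over pixels."""
    c = confusion_counts(pred, true)
    precision = _safe_ratio(c.tp, c.tp + c.fp, reference_empty=c.fn == 0)
    recall = _safe_ratio(c.tp, c.tp + c.fn, reference_empty=c.fp == 0)
    return precision, recall


def classification_report(preds, truths) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, f1) with mutant (1) as positive."""
    preds = np.asarray(preds, dtype=int)
    truths = np.asarray(truths, dtype=int)
    if preds.size == 0 or preds.shape != truths.shape:
        raise ValueError("predictions and truths must be equal-length, non-empty")
    c = confusion_counts(preds, truths)
    accuracy = (c.tp + c.tn) / preds.size
    precision = _safe_ratio(c.tp, c.tp + c.fp, reference_empty=c.fn == 0)
    recall = _safe_ratio(c.tp, c.tp + c.fn, reference_empty=c.fp == 0)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return accuracy, precision, recall, f1
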