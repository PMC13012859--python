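"""Segmentation evaluation metrics.

Pixel-wise overlap metrics (IoU, Dice, F1, accuracy, precision, recall,
specificity), mean absolute error, and the symmetric Hausdorff distance
between mask boundaries.

Two IoU variants are reported: ``iou_foreground`` (lesion class only,
TP/(TP+FP+FN)) and ``iou_all_pixels`` (mean of foreground and background
IoU).  On any binary pair Dice and foreground IoU obey the exact identity
dice = 2*iou/(1+iou), so a Dice far from that of a reported IoU signals
that a different (class-averaged) IoU definition was used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = ["SegMetricsReport", "overlap_metrics", "mae", "hausdorff"]


@dataclass(frozen=True)
class SegMetricsReport:
    iou_foreground: float
    iou_all_pixels: float
    dice: float
    f1: float
    accuracy: float
    precision: float
    recall: float
    specificity: float
    mae: float | None = None
    hausdorff_px: float | None = None
    hausdorff_mm: float | None = None


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:5]}")
    return mask.astype(bool)


def overlap_metrics(pred_mask: np.ndarray, true_mask: np.ndarray) -> SegMetricsReport:
    """Confusion-count based overlap metrics for one binary mask pair."""
    p = _check_binary(pred_mask, "pred_mask")
    t = _check_binary(true_mask, "true_mask")
    if p.shape != t.shape:
        raise ValueError("mask shapes differ")
    tp = float(np.count_nonzero(p & t))
    fp = float(np.count_nonzero(p & ~t))
    fn = float(np.count_nonzero(~p & t))
    tn = float(np.count_nonzero(~p & ~t))

    def safe(num, den, empty=1.0):
        return num / den if den > 0 else empty

    iou_fg = safe(tp, tp + fp + fn)
    iou_bg = safe(tn, tn + fp + fn)
    dice = safe(2 * tp, 2 * tp + fp + fn)
    precision = safe(tp, tp + fp)
    recall = safe(tp, tp + fn)
    f1 = safe(2 * precision * recall, precision + recall, empty=0.0)
    return SegMetricsReport(
        iou_foreground=iou_fg,
        iou_all_pixels=0.5 * (iou_fg + iou_bg),
        dice=dice,
        f1=f1,
        accuracy=(tp + tn) / (tp + tn + fp + fn),
        precision=precision,
        recall=recall,
        specificity=safe(tn, tn + fp),
    )


def mae(pred: np.ndarray, true_mask: np.ndarray, scale: float = 100.0) -> float:
    """Mean absolute error between a probability map and a binary mask,
    multiplied by a reporting scale (default 100, matching the percentage-
    like convention of published MAE figures)."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true_mask, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("shapes differ")
    return float(np.mean(np.abs(pred - true)) * scale)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Coordinates of boundary pixels (mask pixels with a 4-neighbor off)."""
    m = mask.astype(bool)
    eroded = ndimage.binary_erosion(
        m, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]), border_value=0
    )
    return np.argwhere(m & ~eroded)


def hausdorff(pred_mask: np.ndarray, true_mask: np.ndarray, spacing: float = 1.0):
    """Symmetric Hausdorff distance between boundary pixel sets.

    Euclidean distance; returns (distance_px, distance_mm).  Raises on an
    empty mask, where the distance is undefined.
    """
    p = _check_binary(pred_mask, "pred_mask")
    t = _check_binary(true_mask, "true_mask")
    if not p.any() or not t.any():
        raise ValueError("Hausdorff distance undefined for an empty mask")
    bp, bt = _boundary(p), _boundary(t)
    d_pt = cKDTree(bt).query(bp)[0].max()
    d_tp = cKDTree(bp).query(bt)[0].max()
    hd = float(max(d_pt, d_tp))
    return hd, hd * spacing
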