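"""Segmentation metrics: confusion-count scalars (foreground IoU, Dice,
accuracy, specificity, sensitivity) and the 95th-percentile Hausdorff
boundary distance.

The IoU here is the foreground (lesion-class) intersection-over-union,
TP/(TP+FP+FN), as conventionally reported for skin-lesion benchmarks under
the name "mIoU"; a true two-class mean is available behind a flag.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["ConfusionCounts", "confusion", "scalar_metrics", "hd95",
           "evaluate_pair", "write_metrics_csv", "METRIC_NAMES"]

METRIC_NAMES = ("miou", "dsc", "acc", "spe", "sen", "hd95")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_binary(a, name):
    a = np.asarray(a)
    if a.dtype == bool:
        return a
    vals = np.unique(a)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary; found values {vals[:5]}")
    return a.astype(bool)


def confusion(pred, gt) -> ConfusionCounts:
    """Pixelwise confusion counts; the positive class is the lesion (1)."""
    pred = _as_binary(pred, "pred")
    gt = _as_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    tp = int(np.sum(pred & gt))
    fp = int(np.sum(pred & ~gt))
    fn = int(np.sum(~pred & gt))
    tn = int(np.sum(~pred & ~gt))
    return ConfusionCounts(tp, fp, tn, fn)


def _safe(num, den, absent):
    """num/den, with the documented zero-denominator convention: 1.0 when
    the class in question is absent from both maps, else 0.0."""
    if den == 0:
        return 1.0 if absent else 0.0
    return num / den


def scalar_metrics(c: ConfusionCounts, two_class_mean: bool = False) -> dict:
    fg_absent = (c.tp + c.fp + c.fn) == 0
    bg_absent = (c.tn + c.fp + c.fn) == 0
    out = {
        "miou": _safe(c.tp, c.tp + c.fp + c.fn, fg_absent),
        "dsc": _safe(2 * c.tp, 2 * c.tp + c.fp + c.fn, fg_absent),
        "acc": _safe(c.tp + c.tn, c.total, False),
        "spe": _safe(c.tn, c.tn + c.fp, (c.tn + c.fp) == 0),
        "sen": _safe(c.tp, c.tp + c.fn, (c.tp + c.fn) == 0),
    }
    if two_class_mean:
        bg_iou = _safe(c.tn, c.tn + c.fp + c.fn, bg_absent)
        out["miou_2class"] = 0.5 * (out["miou"] + bg_iou)
    return out


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbour."""
    mask = _as_binary(mask, "mask")
    if not mask.any():
        return np.zeros_like(mask)
    struct = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
    interior = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~interior


def hd95(pred, gt, spacing=(1.0, 1.0), percentile: float = 95.0) -> float:
    """Max of the two directed percentile Euclidean boundary distances.

    Distances are evaluated with a Euclidean distance transform of each
    boundary set.  Fallbacks: both masks empty -> 0; exactly one empty ->
    the image diagonal length.
    """
    pred = _as_binary(pred, "pred")
    gt = _as_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if not pred.any() and not gt.any():
        return 0.0
    if not pred.any() or not gt.any():
        ext = np.array(pred.shape) * np.asarray(spacing)
        return float(np.sqrt((ext ** 2).sum()))
    bp = boundary_pixels(pred)
    bg = boundary_pixels(gt)
    d_to_gt = ndimage.distance_transform_edt(~bg, sampling=spacing)
    d_to_pred = ndimage.distance_transform_edt(~bp, sampling=spacing)
    d_pg = d_to_gt[bp]      # pred boundary -> gt boundary
    d_gp = d_to_pred[bg]    # gt boundary -> pred boundary
    return float(max(np.percentile(d_pg, percentile),
                     np.percentile(d_gp, percentile)))


def evaluate_pair(pred, gt) -> dict:
    """All six metrics for one predicted/reference mask pair."""
    out = scalar_metrics(confusion(pred, gt))
    out["hd95"] = hd95(pred, gt)
    return out


def write_metrics_csv(path, rows: list[tuple[str, dict]]):
    """Per-image rows plus one aggregate row (mean ± sd per metric)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(("image",) + METRIC_NAMES)
        for name, m in rows:
            w.writerow([name] + [f"{m[k]:.6f}" for k in METRIC_NAMES])
        if rows:
            vals = {k: np.array([m[k] for _, m in rows]) for k in METRIC_NAMES}
            w.writerow(["mean±sd"] + [f"{vals[k].mean():.6f}±{vals[k].std(ddof=0):.6f}"
                                      for k in METRIC_NAMES])
    return path
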