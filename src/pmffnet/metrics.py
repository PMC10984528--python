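"""Pixel-level segmentation metrics and their dataset-mean aggregation.

From the per-image confusion counts (TP, FP, FN, TN at threshold 0.5):

* accuracy   Acc = (TP + TN) / (TP + TN + FP + FN)
* IoU        IoU = TP / (TP + FP + FN)
* Dice       Dice = (2 TP + s) / (2 TP + FP + FN + s), smooth s = 1 by
  default (set ``smooth=0`` for the plain Dice coefficient)
* precision  Pr = TP / (TP + FP)
* recall     Re = TP / (TP + FN)

Zero-denominator convention: a ratio whose defining sets are both empty
(nothing to find, nothing predicted) counts as 1; a ratio that is undefined
because only one side is empty counts as 0.  The reported mAcc/mIoU/mDice/
mPr/mRe are arithmetic means over images.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "ImageMetrics", "MetricReport", "confusion",
           "metrics_from_counts", "mean_metrics", "write_metrics_csv"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ImageMetrics:
    acc: float
    iou: float
    dice: float
    precision: float
    recall: float

    def as_tuple(self) -> tuple:
        return (self.acc, self.iou, self.dice, self.precision, self.recall)


@dataclass(frozen=True)
class MetricReport:
    """Dataset means (fractions in [0,1]; format with *100 for percent)."""

    m_acc: float
    m_iou: float
    m_dice: float
    m_precision: float
    m_recall: float
    n_images: int

    def as_percent_dict(self) -> dict:
        return {
            "mAcc": round(float(100 * self.m_acc), 2),
            "mIoU": round(float(100 * self.m_iou), 2),
            "mDice": round(float(100 * self.m_dice), 2),
            "mPr": round(float(100 * self.m_precision), 2),
            "mRe": round(float(100 * self.m_recall), 2),
        }


def confusion(gt: np.ndarray, pred_mask: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies between two binary masks of equal shape."""
    gt = np.asarray(gt)
    pred_mask = np.asarray(pred_mask)
    if gt.shape != pred_mask.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred_mask.shape}")
    g = gt.astype(bool)
    p = pred_mask.astype(bool)
    tp = int(np.count_nonzero(g & p))
    fp = int(np.count_nonzero(~g & p))
    fn = int(np.count_nonzero(g & ~p))
    tn = int(np.count_nonzero(~g & ~p))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, both_empty: bool) -> float:
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts, smooth: float = 1.0) -> ImageMetrics:
    empty = c.tp + c.fp + c.fn == 0          # nothing annotated or predicted
    acc = (c.tp + c.tn) / c.total
    iou = _ratio(c.tp, c.tp + c.fp + c.fn, empty)
    dice = (2 * c.tp + smooth) / (2 * c.tp + c.fp + c.fn + smooth) if smooth \
        else _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, empty)
    pr = _ratio(c.tp, c.tp + c.fp, empty)
    re = _ratio(c.tp, c.tp + c.fn, empty)
    return ImageMetrics(acc, iou, dice, pr, re)


def mean_metrics(per_image) -> MetricReport:
    per_image = list(per_image)
    if not per_image:
        raise ValueError("mean_metrics requires at least one image")
    arr = np.array([m.as_tuple() for m in per_image], dtype=np.float64)
    means = arr.mean(axis=0)
    return MetricReport(*means, n_images=len(per_image))


def write_metrics_csv(path, ids, per_image, report: MetricReport):
    """Per-image rows plus a summary row, percentages with 2 decimals."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["id", "Acc", "IoU", "Dice", "Pr", "Re"])
        for sid, m in zip(ids, per_image):
            wr.writerow([sid] + [f"{100 * v:.2f}" for v in m.as_tuple()])
        wr.writerow(["mean"] + [f"{100 * v:.2f}" for v in (
            report.m_acc, report.m_iou, report.m_dice,
            report.m_precision, report.m_recall)])
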