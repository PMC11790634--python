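"""Segmentation metrics: per-class IoU / precision / recall / F1 and
macro means over the four shred classes.

Background (label 4) dominates raw scans, so macro averages computed
over all five classes would be inflated by trivially correct background
points; the macro means here therefore cover classes 0-3 only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..io_model import LabeledPointCloud

log = logging.getLogger(__name__)

N_CLASSES = 5
SHRED_CLASSES = (0, 1, 2, 3)


@dataclass
class ConfusionCounts:
    """Per-class true-positive / false-positive / false-negative counts."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.shape != (N_CLASSES,) or (arr < 0).any():
                raise ValueError(f"{name} must be 5 nonnegative counts")
            setattr(self, name, arr)

    @classmethod
    def from_labels(cls, pred: np.ndarray, truth: np.ndarray) -> "ConfusionCounts":
        pred = np.asarray(pred, dtype=np.int64).ravel()
        truth = np.asarray(truth, dtype=np.int64).ravel()
        if len(pred) != len(truth):
            raise ValueError("pred and truth must have equal lengths")
        cm = np.bincount(truth * N_CLASSES + pred, minlength=N_CLASSES * N_CLASSES)
        cm = cm.reshape(N_CLASSES, N_CLASSES)  # rows truth, cols pred
        tp = np.diag(cm)
        fp = cm.sum(axis=0) - tp
        fn = cm.sum(axis=1) - tp
        return cls(tp, fp, fn)


@dataclass
class MetricsReport:
    """Per-class metrics plus macro means over the shred classes."""

    iou: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    miou: float
    mprecision: float
    mrecall: float
    mf1: float
    counted_classes: tuple[int, ...] = field(default=SHRED_CLASSES)

    def as_dict(self) -> dict:
        return {
            "per_class": {
                int(c): {
                    "iou": float(self.iou[c]),
                    "precision": float(self.precision[c]),
                    "recall": float(self.recall[c]),
                    "f1": float(self.f1[c]),
                }
                for c in range(N_CLASSES)
            },
            "mIoU": self.miou,
            "mPre": self.mprecision,
            "mRec": self.mrecall,
            "F1": self.mf1,
            "counted_classes": list(self.counted_classes),
        }


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def evaluate(
    pred: LabeledPointCloud | np.ndarray, truth: LabeledPointCloud | np.ndarray
) -> MetricsReport:
    """Compare predicted labels with ground truth.

    ``IoU = TP/(TP+FP+FN)``, ``Pre = TP/(TP+FP)``, ``Rec = TP/(TP+FN)``,
    ``F1 = 2*Pre*Rec/(Pre+Rec)`` per class; macro means cover shred
    classes 0-3, and a shred class absent from both prediction and
    truth is excluded from the means (logged).
    """
    pred_labels = pred.labels if isinstance(pred, LabeledPointCloud) else np.asarray(pred)
    true_labels = truth.labels if isinstance(truth, LabeledPointCloud) else np.asarray(truth)
    counts = ConfusionCounts.from_labels(pred_labels, true_labels)
    iou = _safe_div(counts.tp, counts.tp + counts.fp + counts.fn)
    pre = _safe_div(counts.tp, counts.tp + counts.fp)
    rec = _safe_div(counts.tp, counts.tp + counts.fn)
    f1 = _safe_div(2 * pre * rec, pre + rec)

    present = counts.tp + counts.fp + counts.fn > 0
    counted = tuple(c for c in SHRED_CLASSES if present[c])
    skipped = [c for c in SHRED_CLASSES if not present[c]]
    if skipped:
        log.info("evaluate: classes %s absent from pred and truth; excluded from means",
                 skipped)
    if counted:
        sel = list(counted)
        miou, mpre, mrec, mf1 = (float(v[sel].mean()) for v in (iou, pre, rec, f1))
    else:
        miou = mpre = mrec = mf1 = 0.0
    return MetricsReport(iou, pre, rec, f1, miou, mpre, mrec, mf1, counted)
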