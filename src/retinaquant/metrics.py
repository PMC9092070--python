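"""Segmentation agreement metrics from per-class pixel confusion tallies.

PA is the global fraction of correctly labeled pixels; MPA the mean of
per-class recalls; IOU the per-class intersection-over-union; MIOU their
mean.  The published binary (k=2) forms are the special case of the
per-class generalization implemented here — the reduction is proved in
the test-suite.  Classes absent from the truth are excluded from MPA
(and classes absent from both prediction and truth from MIOU) rather
than counted as zero, so sections missing a layer do not deflate scores;
exclusions are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .schema import LabelSchema, SCHEMA

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionTally",
    "MetricsReport",
    "tally",
    "pixel_accuracy",
    "mean_pixel_accuracy",
    "iou",
    "mean_iou",
    "evaluate_pair",
]


@dataclass(frozen=True)
class ConfusionTally:
    """One-vs-rest TP/FP/FN/TN pixel counts for each of k classes."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    def __post_init__(self):
        for arr in (self.tp, self.fp, self.fn, self.tn):
            if np.any(arr < 0):
                raise ValueError("confusion counts must be non-negative")
        totals = self.tp + self.fp + self.fn + self.tn
        if np.unique(totals).size > 1:
            raise ValueError("TP+FP+FN+TN must equal the pixel total for every class")

    @property
    def k(self) -> int:
        return len(self.tp)

    @property
    def n_pixels(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])

    @property
    def truth_counts(self) -> np.ndarray:
        return self.tp + self.fn

    @property
    def pred_counts(self) -> np.ndarray:
        return self.tp + self.fp


def tally(pred: np.ndarray, truth: np.ndarray,
          schema: LabelSchema = SCHEMA) -> ConfusionTally:
    """Count one-vs-rest confusion pixels per class for a prediction pair."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    schema.validate_labels(pred)
    schema.validate_labels(truth)
    k = schema.n_classes
    cm = np.bincount(truth.ravel() * k + pred.ravel(), minlength=k * k).reshape(k, k)
    tp = np.diag(cm).astype(np.int64)
    fp = cm.sum(axis=0) - tp     # predicted c but truth != c
    fn = cm.sum(axis=1) - tp     # truth c but predicted != c
    n = cm.sum()
    tn = n - tp - fp - fn
    return ConfusionTally(tp=tp, fp=fp, fn=fn, tn=tn)


def pixel_accuracy(t: ConfusionTally) -> float:
    """Global per-pixel accuracy (TP+TN)/N — identical for every class."""
    if t.n_pixels == 0:
        raise ValueError("empty tally")
    return float(t.tp.sum()) / t.n_pixels


def per_class_recall(t: ConfusionTally) -> np.ndarray:
    """Per-class recall TP/(TP+FN); NaN where the class is absent from truth."""
    denom = (t.tp + t.fn).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, t.tp / denom, np.nan)


def per_class_accuracy(t: ConfusionTally) -> np.ndarray:
    """Per-class one-vs-rest accuracy (TP+TN)/N."""
    return (t.tp + t.tn) / float(t.n_pixels)


def mean_pixel_accuracy(t: ConfusionTally) -> float:
    """Mean of per-class recalls over classes present in the truth."""
    recalls = per_class_recall(t)
    defined = ~np.isnan(recalls)
    if not defined.any():
        raise ValueError("no class present in truth")
    if not defined.all():
        logger.info("MPA: excluding classes absent from truth: %s",
                    np.nonzero(~defined)[0].tolist())
    return float(np.nanmean(recalls))


def iou(t: ConfusionTally, class_id: int) -> float:
    """TP/(TP+FP+FN) for one class; NaN if absent from both pred and truth."""
    denom = int(t.tp[class_id] + t.fp[class_id] + t.fn[class_id])
    if denom == 0:
        return float("nan")
    return float(t.tp[class_id]) / denom


def per_class_iou(t: ConfusionTally) -> np.ndarray:
    denom = (t.tp + t.fp + t.fn).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, t.tp / denom, np.nan)


def mean_iou(t: ConfusionTally) -> float:
    """Mean of per-class IOU over classes defined in prediction or truth."""
    ious = per_class_iou(t)
    defined = ~np.isnan(ious)
    if not defined.any():
        raise ValueError("no class defined in either prediction or truth")
    if not defined.all():
        logger.info("MIOU: excluding classes absent from both maps: %s",
                    np.nonzero(~defined)[0].tolist())
    return float(np.nanmean(ious))


@dataclass
class MetricsReport:
    """PA/MPA/MIOU plus per-class accuracy, recall and IOU for one tally."""

    pa: float
    mpa: float
    miou: float
    class_accuracy: np.ndarray   # one-vs-rest (TP+TN)/N per class
    class_recall: np.ndarray
    class_iou: np.ndarray

    def as_dict(self, schema: LabelSchema = SCHEMA) -> dict:
        d = {"PA": self.pa, "MPA": self.mpa, "MIOU": self.miou}
        for i, name in enumerate(schema.names):
            d[f"ACC_{name}"] = float(self.class_accuracy[i])
            d[f"RECALL_{name}"] = float(self.class_recall[i])
            d[f"IOU_{name}"] = float(self.class_iou[i])
        return d


def evaluate_pair(pred: np.ndarray, truth: np.ndarray,
                  schema: LabelSchema = SCHEMA) -> MetricsReport:
    t = tally(pred, truth, schema)
    return MetricsReport(
        pa=pixel_accuracy(t),
        mpa=mean_pixel_accuracy(t),
        miou=mean_iou(t),
        class_accuracy=per_class_accuracy(t),
        class_recall=per_class_recall(t),
        class_iou=per_class_iou(t),
    )
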