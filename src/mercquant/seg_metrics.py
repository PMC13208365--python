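"""Pixel-level segmentation evaluation: confusion matrix, IoU, Dice & co.

Predicted masks are compared against reference (manually annotated) masks
pixel by pixel over the three classes background / mitochondria / ER.
Per-class metrics use the one-vs-rest reduction of the 3×3 confusion
matrix:

    precision = TP / (TP + FP)          recall = TP / (TP + FN)
    IoU  = TP / (TP + FP + FN)          F1 = Dice = 2·TP / (2·TP + FP + FN)

with the identity F1 = 2·IoU / (1 + IoU).  Ratios with zero denominators
are reported as undefined (``None``), never silently coerced to 0.

Datasets can be evaluated by pooling pixels from all images into one
confusion matrix (the default) or by averaging per-image metrics, in which
case images where a metric is undefined are skipped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mask_io import LabelMask

__all__ = [
    "CLASS_NAMES",
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion_matrix",
    "class_metrics",
    "dataset_metrics",
]

N_CLASSES = 3
CLASS_NAMES = {0: "background", 1: "mitochondria", 2: "er"}
_METRICS = ("precision", "recall", "iou", "f1")


@dataclass
class ConfusionMatrix:
    """3×3 pixel counts; rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_CLASSES, N_CLASSES) or (c < 0).any():
            raise ValueError("counts must be a non-negative 3x3 integer matrix")
        self.counts = c

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


@dataclass
class ClassMetrics:
    """One-vs-rest counts and derived metrics for a single class.

    Metric fields are ``None`` when their denominator is zero (e.g. the
    class is absent from both masks).
    """

    class_id: int
    tp: int
    fp: int
    fn: int
    tn: int
    precision: Optional[float]
    recall: Optional[float]
    iou: Optional[float]
    f1: Optional[float]


def confusion_matrix(truth: LabelMask, pred: LabelMask) -> ConfusionMatrix:
    """Pixel-wise confusion matrix between a reference and a predicted mask."""
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: truth {truth.shape} vs pred {pred.shape}")
    t = truth.labels.ravel().astype(np.int64)
    p = pred.labels.ravel().astype(np.int64)
    counts = np.bincount(t * N_CLASSES + p, minlength=N_CLASSES * N_CLASSES)
    return ConfusionMatrix(counts.reshape(N_CLASSES, N_CLASSES))


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def class_metrics(
    cm: ConfusionMatrix,
    class_id: int,
    precision_formula: Literal["standard", "as_printed"] = "standard",
) -> ClassMetrics:
    """One-vs-rest metrics for one class from a 3×3 confusion matrix.

    ``precision_formula="as_printed"`` computes precision as
    TP/(TP+FP+FN) — a variant that circulates in some method descriptions
    but coincides with IoU; the standard TP/(TP+FP) is the default.
    """
    if class_id not in CLASS_NAMES:
        raise ValueError(f"class_id must be one of {sorted(CLASS_NAMES)}, got {class_id}")
    c = cm.counts
    tp = int(c[class_id, class_id])
    fp = int(c[:, class_id].sum() - tp)
    fn = int(c[class_id, :].sum() - tp)
    tn = int(c.sum() - tp - fp - fn)
    if precision_formula == "standard":
        precision = _ratio(tp, tp + fp)
    elif precision_formula == "as_printed":
        precision = _ratio(tp, tp + fp + fn)
    else:
        raise ValueError(f"unknown precision_formula {precision_formula!r}")
    return ClassMetrics(
        class_id=class_id,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        precision=precision,
        recall=_ratio(tp, tp + fn),
        iou=_ratio(tp, tp + fp + fn),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
    )


def dataset_metrics(
    pairs: Sequence[Tuple[LabelMask, LabelMask]],
    mode: Literal["pooled", "per_image_mean"] = "pooled",
) -> pd.DataFrame:
    """Per-class metric table over a dataset of (truth, pred) mask pairs.

    ``pooled`` (default) sums the confusion matrices of all images before
    computing metrics; ``per_image_mean`` computes metrics per image and
    averages them, skipping undefined values (skip counts are reported in
    the ``n_skipped_*`` columns and in ``df.attrs["n_images"]``).  A final
    ``macro`` row averages the three class rows.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("dataset_metrics requires at least one (truth, pred) pair")
    rows = {}
    if mode == "pooled":
        pooled = confusion_matrix(*pairs[0])
        for t, p in pairs[1:]:
            pooled = pooled + confusion_matrix(t, p)
        for cid, name in CLASS_NAMES.items():
            m = class_metrics(pooled, cid)
            rows[name] = {k: getattr(m, k) for k in _METRICS}
    elif mode == "per_image_mean":
        per_image = [
            [class_metrics(confusion_matrix(t, p), cid) for cid in CLASS_NAMES]
            for t, p in pairs
        ]
        for cid, name in CLASS_NAMES.items():
            row = {}
            for metric in _METRICS:
                vals = [getattr(ms[cid], metric) for ms in per_image]
                defined = [v for v in vals if v is not None]
                row[metric] = float(np.mean(defined)) if defined else None
                row[f"n_skipped_{metric}"] = len(vals) - len(defined)
            rows[name] = row
    else:
        raise ValueError(f"unknown mode {mode!r}")

    df = pd.DataFrame.from_dict(rows, orient="index")
    macro = {}
    for metric in _METRICS:
        defined = [v for v in df[metric] if v is not None]
        macro[metric] = float(np.mean(defined)) if defined else None
    df.loc["macro"] = pd.Series(macro)
    df.attrs["mode"] = mode
    df.attrs["n_images"] = len(pairs)
    return df
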