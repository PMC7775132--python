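"""Segmentation and classification evaluation.

AOM (area overlap measure) is the Jaccard overlap of a segmentation B
with its reference A, expressed as a percentage:

    AOM(A, B) = S(A ∩ B) / S(A ∪ B) × 100,

with S(.) the pixel count of a region.  ROC curves and AUC summarize a
classifier's score separation between spiculated and non-spiculated
cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn import metrics as _skmetrics

from .imaging_io import Mask2D

__all__ = ["AOMResult", "ROCCurve", "aom", "aom_stack", "roc"]


@dataclass(frozen=True)
class AOMResult:
    value: float  # percent in [0, 100]
    intersection_px: int
    union_px: int


@dataclass(frozen=True)
class ROCCurve:
    points: tuple[tuple[float, float], ...]  # (FPR, TPR), threshold-ordered
    auc: float


def aom(truth: Mask2D, pred: Mask2D) -> AOMResult:
    """Exact integer-count area overlap measure, as a percentage."""
    if (truth.height, truth.width) != (pred.height, pred.width):
        raise ValueError("masks must share dimensions")
    a = truth.pixels.astype(bool)
    b = pred.pixels.astype(bool)
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise ValueError("AOM is undefined for two empty masks")
    return AOMResult(value=100.0 * inter / union, intersection_px=inter, union_px=union)


def aom_stack(truths: Sequence[Mask2D], preds: Sequence[Mask2D]) -> AOMResult:
    """AOM over a slice stack with pooled voxel counts across slices."""
    if len(truths) != len(preds) or not truths:
        raise ValueError("stacks must be equally sized and non-empty")
    inter = union = 0
    for t, p in zip(truths, preds):
        if (t.height, t.width) != (p.height, p.width):
            raise ValueError("masks must share dimensions")
        a = t.pixels.astype(bool)
        b = p.pixels.astype(bool)
        inter += int(np.count_nonzero(a & b))
        union += int(np.count_nonzero(a | b))
    if union == 0:
        raise ValueError("AOM is undefined for empty stacks")
    return AOMResult(value=100.0 * inter / union, intersection_px=inter, union_px=union)


def roc(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """ROC curve with one threshold per distinct score and trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, _thr = _skmetrics.roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(points=tuple(zip(fpr.tolist(), tpr.tolist())),
                    auc=float(_skmetrics.auc(fpr, tpr)))
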