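"""Evaluation metrics: detection rates, overlap scores and landmark error.

Covers the standard detection stack (precision, recall, confusion-matrix
accuracy, average precision as the area under the precision–recall
curve, mAP), the mask-overlap scores (Dice similarity coefficient and
Jaccard index) and landmark agreement against expert annotations
(per-point Euclidean error plus a normalized RMSE).

Undefined metrics (zero denominators, no common landmarks) are reported
as ``None``, never silently coerced to 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidInputError, ShapeMismatchError
from .landmarks import LANDMARK_NAMES, LandmarkSet

__all__ = [
    "ConfusionCounts",
    "precision_recall",
    "accuracy",
    "dice",
    "jaccard",
    "average_precision",
    "mean_ap",
    "PointError",
    "LandmarkErrorReport",
    "landmark_rmse",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def precision_recall(c: ConfusionCounts) -> Tuple[Optional[float], Optional[float]]:
    """Precision TP/(TP+FP) and recall (sensitivity) TP/(TP+FN)."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    return precision, recall


def accuracy(c: ConfusionCounts) -> Optional[float]:
    """Confusion-matrix accuracy (TP+TN)/(TP+FP+TN+FN)."""
    return (c.tp + c.tn) / c.total if c.total > 0 else None


def _binary_pair(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    aa, bb = np.asarray(a).astype(bool), np.asarray(b).astype(bool)
    if aa.shape != bb.shape:
        raise ShapeMismatchError(f"mask shapes differ: {aa.shape} vs {bb.shape}")
    return aa, bb


def dice(a: np.ndarray, b: np.ndarray) -> Optional[float]:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); double-weights the overlap."""
    aa, bb = _binary_pair(a, b)
    denom = int(aa.sum()) + int(bb.sum())
    if denom == 0:
        return None
    return 2.0 * int((aa & bb).sum()) / denom


def jaccard(a: np.ndarray, b: np.ndarray) -> Optional[float]:
    """Jaccard index |A∩B|/|A∪B| (intersection over union)."""
    aa, bb = _binary_pair(a, b)
    union = int((aa | bb).sum())
    if union == 0:
        return None
    return int((aa & bb).sum()) / union


def average_precision(curve: Sequence[Tuple[float, float]]) -> float:
    """Area under a precision–recall curve, AP = ∫ P dR.

    Uses the all-points interpolation rule: precision at each recall is
    replaced by the maximum precision at any recall >= it, then the
    resulting step function is integrated over recall (from recall 0).
    """
    pts = list(curve)
    if not pts:
        raise InvalidInputError("PR curve must contain at least one point")
    recalls = np.asarray([p[0] for p in pts], dtype=float)
    precs = np.asarray([p[1] for p in pts], dtype=float)
    if np.any((recalls < 0) | (recalls > 1)) or np.any((precs < 0) | (precs > 1)):
        raise InvalidInputError("PR curve values must lie in [0, 1]")
    if np.any(np.diff(recalls) < 0):
        raise InvalidInputError("PR curve recalls must be non-decreasing")
    # Interpolated precision: running max from the right.
    interp = np.maximum.accumulate(precs[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recalls, interp):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def mean_ap(class_curves: Sequence[Sequence[Tuple[float, float]]]) -> float:
    """Mean of per-class average precision (standard mAP)."""
    if not class_curves:
        raise InvalidInputError("mAP requires at least one class curve")
    return float(np.mean([average_precision(c) for c in class_curves]))


@dataclass(frozen=True)
class PointError:
    predicted: Tuple[int, int]
    annotated: Tuple[int, int]
    euclidean_px: float
    agreement_pct: float


@dataclass(frozen=True)
class LandmarkErrorReport:
    """Per-point and aggregate agreement between prediction and annotation.

    ``agreement_pct`` is 100·(1 − d/diag), floored at 0, where d is the
    per-point Euclidean pixel error and diag the image diagonal — a
    simple dimensionless agreement score for per-point reporting.
    ``rmse_normalized`` pools all present pairs: coordinates are divided
    by the image dimensions (row/height, col/width) when ``normalized``,
    and the RMSE is taken over all 2n coordinate differences.
    """

    per_point: Dict[str, PointError]
    rmse: float
    normalized: bool
    n: int

    @property
    def rmse_normalized(self) -> float:
        if not self.normalized:
            raise InvalidInputError("report was computed with normalize off")
        return self.rmse


def landmark_rmse(
    pred: LandmarkSet, annot: LandmarkSet, normalize: bool = True
) -> Optional[LandmarkErrorReport]:
    """Compare predicted landmarks with expert annotations.

    Only landmarks present in both sets contribute.  Returns ``None``
    when the two sets share no landmark.
    """
    if (pred.image_height, pred.image_width) != (annot.image_height, annot.image_width):
        raise ShapeMismatchError("landmark sets refer to different image dimensions")
    h, w = pred.image_height, pred.image_width
    diag = math.hypot(h, w)
    per_point: Dict[str, PointError] = {}
    sq_sum = 0.0
    n = 0
    for name in LANDMARK_NAMES:
        p, a = getattr(pred, name), getattr(annot, name)
        if p is None or a is None:
            continue
        dr, dc = p[0] - a[0], p[1] - a[1]
        d_px = math.hypot(dr, dc)
        if normalize:
            sq_sum += (dr / h) ** 2 + (dc / w) ** 2
        else:
            sq_sum += dr * dr + dc * dc
        per_point[name] = PointError(
            predicted=(int(p[0]), int(p[1])),
            annotated=(int(a[0]), int(a[1])),
            euclidean_px=d_px,
            agreement_pct=max(0.0, 100.0 * (1.0 - d_px / diag)),
        )
        n += 1
    if n == 0:
        return None
    rmse = math.sqrt(sq_sum / (2 * n))
    return LandmarkErrorReport(per_point=per_point, rmse=rmse, normalized=normalize, n=n)
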