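"""Alveolar crest (ALC) localization.

The alveolar crest is the most coronal edge of the bone surrounding a
tooth; its distance from the cemento-enamel junction quantifies
radiographic bone loss.  Localization works purely on masks: the tooth
and bone masks are composited, then a k x k window (default 5 x 5) is
swept over every pixel; a window that simultaneously contains
tooth-only pixels and tooth∩bone overlap pixels marks the crest level,
because only there does the tooth emerge from the bone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from . import masks as ma
from .errors import EmptyMaskError, InvalidParameterError, ShapeMismatchError

__all__ = ["KernelHitSet", "sweep_hits", "locate_alc"]

log = logging.getLogger(__name__)

Point = Tuple[int, int]


@dataclass(frozen=True)
class KernelHitSet:
    """Window centers satisfying the crest predicate.

    ``centers`` is an (n, 2) int array of (row, col) sweep positions
    whose clipped kernel window contained at least one tooth-only pixel
    (composite code 1) and at least one overlap pixel (code 3).
    """

    centers: np.ndarray
    kernel_size: int

    def __len__(self) -> int:
        return len(self.centers)


def _check_kernel(kernel_size: int) -> None:
    if (
        not isinstance(kernel_size, (int, np.integer))
        or kernel_size < 3
        or kernel_size % 2 == 0
    ):
        raise InvalidParameterError(
            f"kernel_size must be an odd integer >= 3, got {kernel_size}"
        )


def sweep_hits(comp: np.ndarray, kernel_size: int = 5) -> KernelHitSet:
    """Stride-1 sweep of a k x k window over the composite mask.

    Border windows are clipped at the image edge and still participate.
    An empty hit set (no tooth–bone contact anywhere) is a valid result,
    not an error.
    """
    _check_kernel(kernel_size)
    c = np.asarray(comp)
    if c.ndim != 2 or c.size == 0:
        raise ShapeMismatchError(f"composite must be 2-D non-empty, got {c.shape}")
    # maximum_filter with zero-padding == "window contains" on clipped windows
    has_tooth = ndimage.maximum_filter(
        (c == ma.PRIMARY_ONLY).astype(np.uint8), size=kernel_size, mode="constant", cval=0
    )
    has_overlap = ndimage.maximum_filter(
        (c == ma.OVERLAP).astype(np.uint8), size=kernel_size, mode="constant", cval=0
    )
    centers = np.argwhere((has_tooth & has_overlap).astype(bool))
    return KernelHitSet(centers=centers, kernel_size=int(kernel_size))


def _split_by_centroid(
    centers: np.ndarray, centroid_col: float
) -> Tuple[Optional[Point], Optional[Point]]:
    """Most coronal hit on each side of the tooth axis.

    Left: minimal row among hits with col < centroid (tie: smallest
    col); right: minimal row among hits with col >= centroid (tie:
    largest col).  The crest is by definition the most coronal
    tooth–bone contact, hence minimum row.
    """
    left = right = None
    lmask = centers[:, 1] < centroid_col
    if lmask.any():
        pts = centers[lmask]
        rmin = pts[:, 0].min()
        cands = pts[pts[:, 0] == rmin]
        left = (int(rmin), int(cands[:, 1].min()))
    rmask = ~lmask
    if rmask.any():
        pts = centers[rmask]
        rmin = pts[:, 0].min()
        cands = pts[pts[:, 0] == rmin]
        right = (int(rmin), int(cands[:, 1].max()))
    return left, right


def locate_alc(
    tooth: np.ndarray, bone: np.ndarray, kernel_size: int = 5
) -> Tuple[KernelHitSet, Optional[Point], Optional[Point]]:
    """Locate the left and right alveolar crest points.

    ``tooth`` should already be reduced to its largest instance.
    Returns the raw hit set plus the two reduced landmark points; a side
    with no hits yields ``None``, and fully disjoint masks yield both
    landmarks absent (no bone contact detectable).
    """
    t = np.asarray(tooth)
    b = np.asarray(bone)
    if t.shape != b.shape:
        raise ShapeMismatchError(f"tooth {t.shape} vs bone {b.shape}")
    if not np.any(t):
        raise EmptyMaskError("tooth mask is empty")
    comp = ma.overlay(t, b)
    hits = sweep_hits(comp, kernel_size)
    if len(hits) == 0:
        log.warning("no tooth-bone contact found; ALC landmarks absent")
        return hits, None, None
    centroid_col = float(np.argwhere(np.asarray(t, bool))[:, 1].mean())
    left, right = _split_by_centroid(hits.centers, centroid_col)
    return hits, left, right
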