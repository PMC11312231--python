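"""Cemento-enamel junction (CEJ) localization.

The CEJ is the line where crown enamel meets root cementum.  In mask
terms it is the lower frontier of the crown inside the tooth.  A
predicted crown mask rarely aligns perfectly with the crown portion of
the tooth mask, so the crown is first dilated until it envelops the
tooth's crown portion; the tooth and dilated crown are then composited
and the overlap/tooth-only boundary — which now occurs only at the
crown–root junction — yields the CEJ points on both flanks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from . import masks as ma
from .errors import EmptyMaskError, InvalidParameterError, ShapeMismatchError
from .masks import StructElem

__all__ = ["CejConfig", "DilationResult", "CejResult", "dilate_to_envelop", "locate_cej"]

log = logging.getLogger(__name__)

Point = Tuple[int, int]


@dataclass(frozen=True)
class CejConfig:
    """Crown-dilation policy.

    elem : structuring element of each dilation step.
    max_iterations : hard cap on dilation steps.
    envelop_check : stop as soon as the crown covers every tooth pixel
        coronal to the crown's lowest original row; with the check off,
        exactly ``max_iterations`` steps run.  ``max_iterations=0``
        together with ``envelop_check=False`` disables dilation entirely
        (the ablation baseline).
    """

    elem: StructElem = field(default_factory=StructElem)
    max_iterations: int = 10
    envelop_check: bool = True

    def __post_init__(self) -> None:
        if self.max_iterations < 0:
            raise InvalidParameterError("max_iterations must be >= 0")
        if self.envelop_check and self.max_iterations < 1:
            raise InvalidParameterError(
                "max_iterations must be >= 1 when envelop_check is on"
            )


@dataclass(frozen=True)
class DilationResult:
    mask: np.ndarray
    iterations_used: int
    enveloped: bool


@dataclass(frozen=True)
class CejResult:
    cej_left: Optional[Point]
    cej_right: Optional[Point]
    composite: np.ndarray
    iterations_used: int
    enveloped: bool
    over_dilated: bool


def dilate_to_envelop(
    tooth: np.ndarray, crown: np.ndarray, cfg: CejConfig = CejConfig()
) -> DilationResult:
    """Grow the crown mask until it covers the tooth's crown portion.

    The target region is, per column, every tooth pixel strictly above
    the lowest row of the *original* crown mask in that column (columns
    where the crown is absent impose no constraint).  This reads
    "envelops the crown portion" without knowing the true CEJ and stays
    valid for tilted teeth, where a single global crown-bottom row
    would drag the target onto the downhill root flank.  If the target
    is not covered within ``max_iterations`` the last iterate is
    returned with ``enveloped=False``.
    """
    t = ma._as_binary(tooth)
    c = ma._as_binary(crown)
    if t.shape != c.shape:
        raise ShapeMismatchError(f"tooth {t.shape} vs crown {c.shape}")
    if not t.any() or not c.any():
        raise EmptyMaskError("tooth and crown masks must both be non-empty")

    if not cfg.envelop_check:
        if cfg.max_iterations == 0:
            return DilationResult(c.astype(np.int32), 0, False)
        out = ma.dilate(c, cfg.elem, cfg.max_iterations)
        return DilationResult(out, cfg.max_iterations, False)

    h = t.shape[0]
    rows = np.arange(h)[:, None]
    has_crown = c.any(axis=0)
    lowest = np.where(has_crown, h - 1 - np.argmax(c[::-1, :], axis=0), -1)
    target = t & (rows < lowest[None, :])
    cur = c
    for i in range(cfg.max_iterations + 1):
        if not np.any(target & ~cur):
            return DilationResult(cur.astype(np.int32), i, True)
        if i == cfg.max_iterations:
            break
        cur = ma.dilate(cur, cfg.elem, 1).astype(bool)
    log.warning(
        "crown did not envelop the tooth's crown portion within %d iterations",
        cfg.max_iterations,
    )
    return DilationResult(cur.astype(np.int32), cfg.max_iterations, False)


_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-adjacency


def locate_cej(
    tooth: np.ndarray, crown: np.ndarray, cfg: CejConfig = CejConfig()
) -> CejResult:
    """Locate the left and right CEJ points from tooth and crown masks.

    The junction set J is every overlap pixel (tooth ∩ dilated crown)
    that is 4-adjacent to a tooth-only pixel — the one-pixel-thick lower
    frontier of the crown inside the tooth.  J is split at the tooth's
    centroid column; on the left flank the minimal-column element is
    taken, on the right the maximal-column element (ties broken toward
    the larger, more apical row, since crown over-segmentation errors
    sit coronally).  A crown that swallows the whole tooth leaves no
    frontier: both points are reported absent with ``over_dilated``.
    """
    t = np.asarray(tooth)
    if not np.any(t):
        raise EmptyMaskError("tooth mask is empty")
    dil = dilate_to_envelop(t, crown, cfg)
    comp = ma.overlay(t, dil.mask)
    tooth_only = comp == ma.PRIMARY_ONLY
    overlap = comp == ma.OVERLAP
    near_tooth_only = ndimage.binary_dilation(tooth_only, structure=_CROSS)
    junction = np.argwhere(overlap & near_tooth_only)

    if len(junction) == 0:
        log.warning("crown covers the entire tooth; CEJ landmarks absent")
        return CejResult(None, None, comp, dil.iterations_used, dil.enveloped, True)

    centroid_col = float(np.argwhere(t.astype(bool))[:, 1].mean())
    left = right = None
    lmask = junction[:, 1] < centroid_col
    if lmask.any():
        pts = junction[lmask]
        cmin = pts[:, 1].min()
        cands = pts[pts[:, 1] == cmin]
        left = (int(cands[:, 0].max()), int(cmin))
    rmask = ~lmask
    if rmask.any():
        pts = junction[rmask]
        cmax = pts[:, 1].max()
        cands = pts[pts[:, 1] == cmax]
        right = (int(cands[:, 0].max()), int(cmax))
    return CejResult(left, right, comp, dil.iterations_used, dil.enveloped, False)
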