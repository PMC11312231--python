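"""Seeded synthetic periapical scenes with known ground truth.

Every stage of the pipeline is testable without clinical data: each
generated case bundles clean tooth/bone/crown masks, corrupted
("predicted") variants emulating segmenter imperfections, a noisy
low-contrast grayscale render, and the exact CEJ/ALC landmark
positions implied by the construction.

Scene model
-----------
A single-rooted tooth is rasterized as a vertically symmetric profile:
an elliptically rounded crown cap, a constant-width crown body down to
the CEJ row, then a linearly tapering root to the apex.  The crown mask
is the tooth above the CEJ row.  The bone is a full-width band starting
at the crest row, overlapping the outer ``bone_overlap_px`` of the
tooth flank (radiographically, bone superimposes over the root) so the
most coronal tooth–bone contact sits exactly at ``bone_crest_row``.
The whole scene may be tilted; ground-truth landmarks are transformed
analytically by the same rotation.

Corruption emulates imperfect predicted masks: binary erosion, a 1-px
random rigid shift per mask, and partial "neighboring teeth" blobs at
the image borders added to the predicted tooth mask only (exercising
largest-instance retention).  The grayscale render compresses contrast
into [80, 170] and adds Gaussian plus salt-and-pepper noise, giving the
enhancement stage something to do.

All randomness flows from the single integer ``seed`` through one
``numpy`` generator; identical parameters give bit-identical cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .landmarks import LandmarkSet
from .masks import StructElem, erode

__all__ = ["SceneParams", "SyntheticCase", "generate_case", "generate_suite"]

_SALT_PEPPER_FRAC = 0.05
_BG_LEVEL, _BONE_LEVEL, _TOOTH_LEVEL = 85, 125, 168


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene (all distances in pixels)."""

    canvas: Tuple[int, int] = (256, 256)
    tooth_center_col: int = 128
    crown_width: int = 90
    root_tip_width: int = 30
    crown_top_row: int = 30
    cej_row: int = 110
    root_tip_row: int = 230
    bone_crest_row: int = 150
    tilt_deg: float = 0.0
    mask_erosion_px: int = 0
    distractor_teeth: int = 0
    noise_sigma: float = 8.0
    bone_overlap_px: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.canvas
        if h < 32 or w < 32:
            raise InvalidParameterError("canvas must be at least 32x32")
        if not (self.crown_top_row < self.cej_row < self.root_tip_row <= h):
            raise InvalidParameterError(
                "require crown_top_row < cej_row < root_tip_row <= canvas height"
            )
        if not (self.cej_row <= self.bone_crest_row):
            raise InvalidParameterError(
                "require cej_row <= bone_crest_row (crest at or apical to CEJ)"
            )
        if self.root_tip_width > self.crown_width:
            raise InvalidParameterError("root tip cannot be wider than the crown")
        if min(self.crown_width, self.root_tip_width) < 4:
            raise InvalidParameterError("tooth widths must be >= 4 px")
        if self.mask_erosion_px < 0 or self.distractor_teeth < 0:
            raise InvalidParameterError("corruption parameters must be non-negative")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be non-negative")
        if self.bone_overlap_px < 1:
            raise InvalidParameterError("bone_overlap_px must be >= 1")


@dataclass(frozen=True)
class SyntheticCase:
    image: np.ndarray
    tooth: np.ndarray
    bone: np.ndarray
    crown: np.ndarray
    tooth_pred: np.ndarray
    bone_pred: np.ndarray
    crown_pred: np.ndarray
    truth: LandmarkSet
    params: SceneParams


def _half_width(p: SceneParams, row: int) -> float:
    """Tooth half-width at a given row of the untilted profile."""
    crown_half = p.crown_width / 2.0
    tip_half = p.root_tip_width / 2.0
    cap = max(2, (p.cej_row - p.crown_top_row) // 3)
    if row < p.crown_top_row or row > p.root_tip_row:
        return 0.0
    if row < p.crown_top_row + cap:
        t = (row - p.crown_top_row + 1) / cap  # elliptical crown cap
        return crown_half * math.sqrt(max(0.0, 1.0 - (1.0 - t) ** 2))
    if row < p.cej_row:
        return crown_half
    s = (row - p.cej_row) / max(1, p.root_tip_row - p.cej_row)
    return crown_half + (tip_half - crown_half) * s


def _rasterize_tooth(p: SceneParams) -> np.ndarray:
    h, w = p.canvas
    tooth = np.zeros((h, w), dtype=np.int32)
    for r in range(p.crown_top_row, min(p.root_tip_row + 1, h)):
        half = _half_width(p, r)
        if half < 0.5:
            continue
        c0 = max(0, int(round(p.tooth_center_col - half)))
        c1 = min(w - 1, int(round(p.tooth_center_col + half)))
        tooth[r, c0:c1 + 1] = 1
    return tooth


def _flank_cols(tooth: np.ndarray, row: int) -> Optional[Tuple[int, int]]:
    cols = np.flatnonzero(tooth[row])
    if cols.size == 0:
        return None
    return int(cols[0]), int(cols[-1])


def _rotate_mask(mask: np.ndarray, angle_deg: float) -> np.ndarray:
    if angle_deg == 0.0:
        return mask.copy()
    return ndimage.rotate(
        mask.astype(np.uint8), angle_deg, reshape=False, order=0, mode="constant", cval=0
    ).astype(np.int32)


def _rotate_point(
    point: Tuple[int, int], angle_deg: float, shape: Tuple[int, int]
) -> Tuple[int, int]:
    """Analytic counterpart of :func:`_rotate_mask` for a single point."""
    if angle_deg == 0.0:
        return point
    h, w = shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    th = math.radians(angle_deg)
    dr, dc = point[0] - cr, point[1] - cc
    r = cr + math.cos(th) * dr - math.sin(th) * dc
    c = cc + math.sin(th) * dr + math.cos(th) * dc
    return (
        int(np.clip(round(r), 0, h - 1)),
        int(np.clip(round(c), 0, w - 1)),
    )


def _shift_mask(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Rigid shift with zero fill (no wrap-around)."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    src_r = slice(max(0, -dr), min(h, h - dr))
    dst_r = slice(max(0, dr), min(h, h + dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = mask[src_r, src_c]
    return out


def _corrupt(mask: np.ndarray, erosion_px: int, rng: np.random.Generator) -> np.ndarray:
    if erosion_px == 0:
        return mask.copy()
    # border_value=1: structures touching the frame are not eaten from outside
    out = erode(mask, StructElem("square", 1), erosion_px, border_value=1)
    dr, dc = (int(v) for v in rng.integers(-1, 2, size=2))
    return _shift_mask(np.asarray(out, dtype=np.int32), dr, dc)


def _add_distractors(
    tooth_pred: np.ndarray, n: int, p: SceneParams, rng: np.random.Generator
) -> np.ndarray:
    """Partial neighbor-tooth blobs hugging the left/right image borders."""
    h, w = tooth_pred.shape
    out = tooth_pred.copy()
    yy, xx = np.mgrid[0:h, 0:w]
    mid = (p.crown_top_row + p.root_tip_row) // 2
    for k in range(n):
        side = k % 2
        cc = 6 if side == 0 else w - 7
        cr = mid + int(rng.integers(-20, 21))
        a, b = 32, 9  # semi-axes (rows, cols)
        ell = ((yy - cr) / a) ** 2 + ((xx - cc) / b) ** 2 <= 1.0
        out |= ell.astype(np.int32)
    return out


def generate_case(params: SceneParams) -> SyntheticCase:
    """Build one fully determined synthetic scene from its parameters."""
    p = params
    h, w = p.canvas
    rng = np.random.default_rng(p.seed)

    tooth0 = _rasterize_tooth(p)
    crown0 = tooth0 * (np.arange(h)[:, None] < p.cej_row)

    band = (np.arange(h)[:, None] >= p.bone_crest_row) & np.ones((1, w), dtype=bool)
    interior = erode(tooth0, StructElem("square", 1), p.bone_overlap_px, border_value=1)
    bone0 = (band & ~interior.astype(bool)).astype(np.int32)

    cej_flanks = _flank_cols(tooth0, p.cej_row)
    alc_flanks = _flank_cols(tooth0, min(p.bone_crest_row, h - 1))

    tooth = _rotate_mask(tooth0, p.tilt_deg)
    crown = _rotate_mask(crown0, p.tilt_deg)
    bone = _rotate_mask(bone0, p.tilt_deg)

    def _pt(row: int, col: Optional[int]) -> Optional[Tuple[int, int]]:
        if col is None:
            return None
        return _rotate_point((row, col), p.tilt_deg, (h, w))

    truth = LandmarkSet(
        image_height=h,
        image_width=w,
        cej_left=_pt(p.cej_row, cej_flanks[0] if cej_flanks else None),
        cej_right=_pt(p.cej_row, cej_flanks[1] if cej_flanks else None),
        alc_left=_pt(p.bone_crest_row, alc_flanks[0] if alc_flanks else None),
        alc_right=_pt(p.bone_crest_row, alc_flanks[1] if alc_flanks else None),
    )

    tooth_pred = _corrupt(tooth, p.mask_erosion_px, rng)
    bone_pred = _corrupt(bone, p.mask_erosion_px, rng)
    crown_pred = _corrupt(crown, p.mask_erosion_px, rng)
    if p.distractor_teeth > 0:
        tooth_pred = _add_distractors(tooth_pred, p.distractor_teeth, p, rng)

    img = np.full((h, w), float(_BG_LEVEL))
    img[bone.astype(bool)] = _BONE_LEVEL
    img[tooth.astype(bool)] = _TOOTH_LEVEL
    if p.noise_sigma > 0:
        img += rng.normal(0.0, p.noise_sigma, size=img.shape)
    n_sp = int(round(_SALT_PEPPER_FRAC * img.size))
    if n_sp > 0:
        flat_idx = rng.choice(img.size, size=n_sp, replace=False)
        vals = rng.integers(0, 2, size=n_sp) * 255
        img.ravel()[flat_idx] = vals
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return SyntheticCase(
        image=image,
        tooth=tooth,
        bone=bone,
        crown=crown,
        tooth_pred=tooth_pred,
        bone_pred=bone_pred,
        crown_pred=crown_pred,
        truth=truth,
        params=p,
    )


def default_suite_base() -> SceneParams:
    """Corruption conditions used by the standard evaluation suite."""
    return SceneParams(mask_erosion_px=2, distractor_teeth=2)


def generate_suite(
    n: int, base: Optional[SceneParams] = None, seed: int = 0
) -> List[SyntheticCase]:
    """Draw ``n`` cases around ``base`` with varied anatomy and tilt.

    Per case: the CEJ row varies by ±10%, the crest row spans mild to
    severe bone loss (10–70 px apical to the CEJ), and the whole scene
    tilts uniformly in [-10°, 10°].  Reproducible given (n, base, seed).
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if base is None:
        base = default_suite_base()
    rng = np.random.default_rng(seed)
    h = base.canvas[0]
    cases = []
    for _ in range(n):
        cej = int(round(base.cej_row * (1.0 + rng.uniform(-0.1, 0.1))))
        cej = int(np.clip(cej, base.crown_top_row + 15, base.root_tip_row - 40))
        crest = cej + int(rng.integers(10, 71))
        crest = min(crest, base.root_tip_row - 10, h - 1)
        tilt = float(rng.uniform(-10.0, 10.0))
        case_seed = int(rng.integers(0, 2**31 - 1))
        params = replace(
            base, cej_row=cej, bone_crest_row=crest, tilt_deg=tilt, seed=case_seed
        )
        cases.append(generate_case(params))
    return cases
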