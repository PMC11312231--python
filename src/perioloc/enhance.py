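"""Radiograph preprocessing: median denoising followed by CLAHE.

Periapical radiographs are noisy and low-contrast; contours of enamel,
root and alveolar bone benefit from local contrast stretching.  The
pipeline here is deliberately minimal and order-fixed: a median filter
first (so impulse noise is not amplified by the equalization), then
contrast-limited adaptive histogram equalization (CLAHE).

CLAHE implementation notes
--------------------------
The image is split into a grid of tiles (integer division; the last row
and column of tiles absorb any remainder).  Each tile's 256-bin
histogram is clipped at ``clip_limit * tile_pixels / 256`` with the
excess redistributed uniformly over all bins, an equalization lookup
table is built from the clipped CDF, and every output pixel is the
bilinear blend of the four surrounding tile LUTs (clamped to the
nearest tile beyond the outermost tile centers).  With a single tile
and a non-binding clip limit this reduces exactly to global histogram
equalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["EnhanceParams", "median_denoise", "clahe", "enhance"]

_BINS = 256


@dataclass(frozen=True)
class EnhanceParams:
    """Preprocessing parameters.

    median_kernel : odd window side of the median filter, in pixels.
    clahe_clip_limit : histogram clip factor (relative to the uniform
        bin height); larger values allow more contrast amplification.
    clahe_tiles : tile grid as (rows, cols).
    apply_median / apply_clahe : stage toggles for ablations.
    """

    median_kernel: int = 3
    clahe_clip_limit: float = 2.0
    clahe_tiles: Tuple[int, int] = (8, 8)
    apply_median: bool = True
    apply_clahe: bool = True

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise InvalidParameterError(
                f"median_kernel must be odd and >= 1, got {self.median_kernel}"
            )
        if not self.clahe_clip_limit > 0:
            raise InvalidParameterError("clahe_clip_limit must be > 0")
        if min(self.clahe_tiles) < 1:
            raise InvalidParameterError("tile counts must be >= 1")


def _as_gray(image: np.ndarray) -> np.ndarray:
    a = np.asarray(image)
    if a.ndim != 2 or a.size == 0:
        raise InvalidInputError(f"expected a non-empty 2-D image, got shape {a.shape}")
    if a.dtype != np.uint8:
        if np.any((a < 0) | (a > 255)):
            raise InvalidInputError("image values must lie in [0, 255]")
        a = a.astype(np.uint8)
    return a


def median_denoise(image: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median-filter an 8-bit image with a ``kernel`` x ``kernel`` window.

    Borders are edge-replicated so no artificial dark frame is
    introduced ahead of CLAHE.  ``kernel`` must be odd, positive and no
    larger than the smaller image side.
    """
    img = _as_gray(image)
    if not isinstance(kernel, (int, np.integer)) or kernel < 1 or kernel % 2 == 0:
        raise InvalidParameterError(f"kernel must be a positive odd integer, got {kernel}")
    if kernel > min(img.shape):
        raise InvalidParameterError(
            f"kernel {kernel} exceeds image extent {min(img.shape)}"
        )
    if kernel == 1:
        return img.copy()
    return ndimage.median_filter(img, size=kernel, mode="nearest")


def _tile_edges(extent: int, tiles: int) -> np.ndarray:
    """Tile boundary offsets along one axis; the last tile absorbs the remainder."""
    size = extent // tiles
    if size < 1:
        raise InvalidParameterError(
            f"tile grid too fine: {tiles} tiles over {extent} pixels"
        )
    edges = np.arange(tiles + 1) * size
    edges[-1] = extent
    return edges


def clahe(
    image: np.ndarray,
    clip_limit: float = 2.0,
    tiles: Tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of an 8-bit image."""
    img = _as_gray(image)
    if not clip_limit > 0:
        raise InvalidParameterError("clip_limit must be > 0")
    trows, tcols = int(tiles[0]), int(tiles[1])
    if trows < 1 or tcols < 1:
        raise InvalidParameterError("tile counts must be >= 1")
    h, w = img.shape
    redges = _tile_edges(h, trows)
    cedges = _tile_edges(w, tcols)

    luts = np.empty((trows, tcols, _BINS), dtype=np.float64)
    centers_r = np.empty(trows)
    centers_c = np.empty(tcols)
    for i in range(trows):
        centers_r[i] = (redges[i] + redges[i + 1] - 1) / 2.0
    for j in range(tcols):
        centers_c[j] = (cedges[j] + cedges[j + 1] - 1) / 2.0

    for i in range(trows):
        for j in range(tcols):
            tile = img[redges[i]:redges[i + 1], cedges[j]:cedges[j + 1]]
            npix = tile.size
            hist = np.bincount(tile.ravel(), minlength=_BINS).astype(np.float64)
            clip = clip_limit * npix / _BINS
            excess = np.sum(np.maximum(hist - clip, 0.0))
            if excess > 0:
                hist = np.minimum(hist, clip) + excess / _BINS
            cdf = np.cumsum(hist)
            luts[i, j] = 255.0 * cdf / npix

    # Bilinear blend of the four surrounding tile LUTs, clamped to the
    # edge tiles outside the outermost centers.
    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    i1 = np.clip(np.searchsorted(centers_r, rows), 0, trows - 1)
    i0 = np.clip(i1 - 1, 0, trows - 1)
    j1 = np.clip(np.searchsorted(centers_c, cols), 0, tcols - 1)
    j0 = np.clip(j1 - 1, 0, tcols - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        wr = np.where(
            i1 > i0,
            (rows - centers_r[i0]) / (centers_r[i1] - centers_r[i0]),
            0.0,
        )
        wc = np.where(
            j1 > j0,
            (cols - centers_c[j0]) / (centers_c[j1] - centers_c[j0]),
            0.0,
        )
    wr = np.clip(wr, 0.0, 1.0)[:, None]
    wc = np.clip(wc, 0.0, 1.0)[None, :]

    I0 = i0[:, None]
    I1 = i1[:, None]
    J0 = j0[None, :]
    J1 = j1[None, :]
    out = (
        (1 - wr) * (1 - wc) * luts[np.broadcast_to(I0, img.shape),
                                   np.broadcast_to(J0, img.shape), img]
        + (1 - wr) * wc * luts[np.broadcast_to(I0, img.shape),
                               np.broadcast_to(J1, img.shape), img]
        + wr * (1 - wc) * luts[np.broadcast_to(I1, img.shape),
                               np.broadcast_to(J0, img.shape), img]
        + wr * wc * luts[np.broadcast_to(I1, img.shape),
                         np.broadcast_to(J1, img.shape), img]
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def enhance(image: np.ndarray, params: EnhanceParams = EnhanceParams()) -> np.ndarray:
    """Full preprocessing: median filter first, CLAHE second.

    The order is fixed — residual impulse noise left for CLAHE would be
    amplified into high-contrast speckle.
    """
    img = _as_gray(image)
    if params.apply_median:
        img = median_denoise(img, params.median_kernel)
    if params.apply_clahe:
        img = clahe(img, params.clahe_clip_limit, params.clahe_tiles)
    return img
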