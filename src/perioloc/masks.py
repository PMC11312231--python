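"""Mask algebra: the primitives the landmark locators are built from.

A *label mask* is a 2-D integer array where 0 is background and each
positive value is one object instance; a *binary mask* is the {0,1}
special case.  Instance masks produced by any segmenter (the package is
segmenter-agnostic) are post-processed with these operations before
landmark localization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk as _disk

from .errors import (
    EmptyMaskError,
    InvalidInputError,
    InvalidParameterError,
    ShapeMismatchError,
)

__all__ = [
    "StructElem",
    "connected_components",
    "retain_largest",
    "relabel",
    "dilate",
    "erode",
    "overlay",
]

# CompositeMask codes produced by `overlay`.
BG, PRIMARY_ONLY, SECONDARY_ONLY, OVERLAP = 0, 1, 2, 3


@dataclass(frozen=True)
class StructElem:
    """Structuring element for morphology: square, cross or disk of given radius."""

    shape: str = "square"
    radius: int = 1

    def __post_init__(self) -> None:
        if self.shape not in ("square", "cross", "disk"):
            raise InvalidParameterError(f"unknown element shape {self.shape!r}")
        if self.radius < 1:
            raise InvalidParameterError("radius must be >= 1")

    def footprint(self) -> np.ndarray:
        r = self.radius
        if self.shape == "square":
            return np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
        if self.shape == "cross":
            yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
            return (np.abs(yy) + np.abs(xx)) <= r
        return _disk(r).astype(bool)

    @classmethod
    def parse(cls, text: str) -> "StructElem":
        """Parse ``"shape:radius"`` (e.g. ``"square:1"``)."""
        try:
            shape, radius = text.split(":")
            return cls(shape=shape, radius=int(radius))
        except (ValueError, TypeError) as e:
            raise InvalidParameterError(f"cannot parse structuring element {text!r}") from e


def _as_labels(mask: np.ndarray) -> np.ndarray:
    a = np.asarray(mask)
    if a.ndim != 2 or a.size == 0:
        raise InvalidInputError(f"expected a non-empty 2-D mask, got shape {a.shape}")
    if not np.issubdtype(a.dtype, np.integer) and a.dtype != bool:
        raise InvalidInputError(f"mask dtype must be integer, got {a.dtype}")
    if a.dtype != bool and np.any(a < 0):
        raise InvalidInputError("label values must be non-negative")
    return a.astype(np.int32)


def _as_binary(mask: np.ndarray) -> np.ndarray:
    a = _as_labels(mask)
    if np.any(a > 1):
        raise InvalidInputError("binary mask must contain only {0, 1}")
    return a.astype(bool)


def connected_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label connected foreground regions, 1..n in raster discovery order."""
    m = _as_binary(mask)
    if connectivity not in (4, 8):
        raise InvalidParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, n = ndimage.label(m, structure=structure)
    if n == 0:
        return labels.astype(np.int32)
    # Normalize to raster-scan first-occurrence order.
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    idx = np.flatnonzero(flat)
    np.minimum.at(first, flat[idx], idx)
    order = np.argsort(first[1:], kind="stable")  # old labels ranked by first pixel
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order + 1] = np.arange(1, n + 1)
    return remap[labels]


def retain_largest(mask: np.ndarray) -> np.ndarray:
    """Keep only the instance with the largest pixel area, binarized.

    A single-tooth crop should contain one complete tooth covering most
    of the masked area; fragments of neighboring teeth are discarded by
    keeping the label with the maximal pixel count (ties broken toward
    the smallest label value).
    """
    m = _as_labels(mask)
    counts = np.bincount(m.ravel())
    if counts[1:].sum() == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    winner = int(np.argmax(counts[1:])) + 1  # argmax takes the first (smallest) label on ties
    return (m == winner).astype(np.int32)


def extract_main_instance(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Largest instance of an arbitrary label mask, binarized.

    Instance masks with distinct labels are reduced directly with
    :func:`retain_largest`; a binary mask is first split into connected
    components so detached fragments count as separate instances.
    """
    m = _as_labels(mask)
    if m.max(initial=0) <= 1:
        m = connected_components(m, connectivity)
    return retain_largest(m)


def relabel(mask: np.ndarray, new_value: int) -> np.ndarray:
    """Assign ``new_value`` to every foreground pixel of a binary mask."""
    if not isinstance(new_value, (int, np.integer)) or new_value < 1:
        raise InvalidParameterError(f"new_value must be a positive integer, got {new_value}")
    m = _as_binary(mask)
    return np.where(m, np.int32(new_value), np.int32(0))


def dilate(mask: np.ndarray, elem: StructElem = StructElem(), iterations: int = 1) -> np.ndarray:
    """Minkowski dilation A ⊕ B, applied ``iterations`` times, clipped at borders."""
    if not isinstance(iterations, (int, np.integer)) or iterations < 1:
        raise InvalidParameterError(f"iterations must be >= 1, got {iterations}")
    m = _as_binary(mask)
    out = ndimage.binary_dilation(m, structure=elem.footprint(), iterations=int(iterations))
    return out.astype(np.int32)


def erode(mask: np.ndarray, elem: StructElem = StructElem(), iterations: int = 1,
          border_value: int = 0) -> np.ndarray:
    """Binary erosion; the dual of :func:`dilate` (used for mask corruption)."""
    if not isinstance(iterations, (int, np.integer)) or iterations < 1:
        raise InvalidParameterError(f"iterations must be >= 1, got {iterations}")
    m = _as_binary(mask)
    out = ndimage.binary_erosion(
        m, structure=elem.footprint(), iterations=int(iterations),
        border_value=border_value,
    )
    return out.astype(np.int32)


def overlay(primary: np.ndarray, secondary: np.ndarray) -> np.ndarray:
    """Composite two binary masks into the 4-code label image.

    Codes: 0 background, 1 primary-only, 2 secondary-only, 3 overlap.
    Masks from one segmenter may share raw pixel values, so compositing
    is done on relabeled codes that cannot collide by construction.
    """
    p = _as_binary(primary)
    s = _as_binary(secondary)
    if p.shape != s.shape:
        raise ShapeMismatchError(f"mask shapes differ: {p.shape} vs {s.shape}")
    return (p.astype(np.int32) + 2 * s.astype(np.int32))
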