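"""File formats: grayscale images, label masks, landmark JSON, CSV reports.

Masks travel as single-channel PNG with label values preserved verbatim
(16-bit PNG when any label exceeds 255).  Landmarks travel as JSON with
0-based (row, col) integer coordinates plus the image dimensions, so a
normalized RMSE is computable from the file alone.  All writers create
parent directories; all readers validate and fail loudly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import numpy as np
from PIL import Image

from .errors import InvalidInputError, SchemaError
from .landmarks import LandmarkSet
from .metrics import LandmarkErrorReport

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_landmarks",
    "write_landmarks",
    "write_report",
]


def _ensure_parent(path: PathLike) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p


def read_image(path: PathLike) -> np.ndarray:
    """Read an 8-bit grayscale image; color inputs are luma-converted with a warning."""
    try:
        im = Image.open(path)
    except OSError as e:
        raise InvalidInputError(f"cannot read image {path}: {e}") from e
    if im.mode not in ("L", "I;16", "I"):
        log.warning("converting %s-mode image %s to grayscale by luma weighting", im.mode, path)
        im = im.convert("L")
    a = np.asarray(im)
    if a.dtype != np.uint8:
        if a.max(initial=0) > 255:
            raise InvalidInputError(f"{path}: not an 8-bit grayscale image")
        a = a.astype(np.uint8)
    return a


def write_image(image: np.ndarray, path: PathLike) -> None:
    a = np.asarray(image)
    if a.ndim != 2:
        raise InvalidInputError("image must be 2-D grayscale")
    Image.fromarray(a.astype(np.uint8), mode="L").save(_ensure_parent(path))


def read_mask(path: PathLike) -> np.ndarray:
    """Read a label mask PNG (8- or 16-bit single channel) as int32."""
    try:
        im = Image.open(path)
    except OSError as e:
        raise InvalidInputError(f"cannot read mask {path}: {e}") from e
    if im.mode not in ("L", "I;16", "I", "P"):
        raise InvalidInputError(
            f"{path}: mask must be single-channel integer PNG, got mode {im.mode}"
        )
    if im.mode == "P":
        im = im.convert("L")
    a = np.asarray(im).astype(np.int32)
    if a.ndim != 2 or np.any(a < 0):
        raise InvalidInputError(f"{path}: mask must be 2-D with non-negative labels")
    return a


def write_mask(mask: np.ndarray, path: PathLike) -> None:
    a = np.asarray(mask)
    if a.ndim != 2 or np.any(a < 0):
        raise InvalidInputError("mask must be 2-D with non-negative labels")
    p = _ensure_parent(path)
    if a.max(initial=0) > 255:
        if a.max() > 65535:
            raise InvalidInputError("label values above 65535 are not storable as PNG")
        Image.fromarray(a.astype(np.uint16)).save(p)
    else:
        Image.fromarray(a.astype(np.uint8), mode="L").save(p)


def read_landmarks(path: PathLike) -> LandmarkSet:
    try:
        with open(path) as f:
            d = json.load(f)
    except (OSError, json.JSONDecodeError) as e:
        raise SchemaError(f"cannot read landmark JSON {path}: {e}") from e
    return LandmarkSet.from_dict(d)


def write_landmarks(landmarks: LandmarkSet, path: PathLike, **extra) -> None:
    """Write a landmark set (plus optional extra fields, e.g. hit lists)."""
    d = landmarks.to_dict()
    d.update(extra)
    with open(_ensure_parent(path), "w") as f:
        json.dump(d, f, indent=2, sort_keys=True)
        f.write("\n")


def write_report(report: LandmarkErrorReport, path: PathLike) -> None:
    """CSV: one row per landmark pair, footer row with the pooled RMSE."""
    lines = ["landmark,pred_row,pred_col,annot_row,annot_col,euclidean_px,agreement_pct"]
    for name, pe in report.per_point.items():
        lines.append(
            f"{name},{pe.predicted[0]},{pe.predicted[1]},"
            f"{pe.annotated[0]},{pe.annotated[1]},"
            f"{pe.euclidean_px:.6f},{pe.agreement_pct:.6f}"
        )
    kind = "rmse_normalized" if report.normalized else "rmse_px"
    lines.append(f"{kind},,,,,{report.rmse:.6f},")
    Path(_ensure_parent(path)).write_text("\n".join(lines) + "\n")
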