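"""End-to-end mask-to-landmarks pipeline and its configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from .alc import locate_alc
from .cej import CejConfig, locate_cej
from .enhance import EnhanceParams
from .errors import InvalidParameterError, SchemaError, ShapeMismatchError
from .landmarks import LandmarkSet
from .masks import StructElem, extract_main_instance

__all__ = ["PipelineConfig", "run_pipeline"]

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Everything configurable about the mask-to-landmarks run."""

    enhance: EnhanceParams = field(default_factory=EnhanceParams)
    alc_kernel: int = 5
    cej: CejConfig = field(default_factory=CejConfig)
    normalize_rmse: bool = True
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.alc_kernel < 3 or self.alc_kernel % 2 == 0:
            raise InvalidParameterError("alc_kernel must be odd and >= 3")
        if self.connectivity not in (4, 8):
            raise InvalidParameterError("connectivity must be 4 or 8")

    def to_yaml(self) -> str:
        d = {
            "schema_version": _SCHEMA_VERSION,
            "enhance": asdict(self.enhance),
            "alc_kernel": self.alc_kernel,
            "cej": {
                "elem": f"{self.cej.elem.shape}:{self.cej.elem.radius}",
                "max_iterations": self.cej.max_iterations,
                "envelop_check": self.cej.envelop_check,
            },
            "normalize_rmse": self.normalize_rmse,
            "connectivity": self.connectivity,
        }
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise SchemaError("config file must contain a mapping")
        if d.get("schema_version") != _SCHEMA_VERSION:
            raise SchemaError(f"unsupported config schema_version {d.get('schema_version')!r}")
        try:
            e = d["enhance"]
            enhance = EnhanceParams(
                median_kernel=int(e["median_kernel"]),
                clahe_clip_limit=float(e["clahe_clip_limit"]),
                clahe_tiles=tuple(e["clahe_tiles"]),
                apply_median=bool(e.get("apply_median", True)),
                apply_clahe=bool(e.get("apply_clahe", True)),
            )
            c = d["cej"]
            cej = CejConfig(
                elem=StructElem.parse(c["elem"]),
                max_iterations=int(c["max_iterations"]),
                envelop_check=bool(c["envelop_check"]),
            )
            return cls(
                enhance=enhance,
                alc_kernel=int(d["alc_kernel"]),
                cej=cej,
                normalize_rmse=bool(d["normalize_rmse"]),
                connectivity=int(d["connectivity"]),
            )
        except KeyError as exc:
            raise SchemaError(f"config missing field {exc.args[0]!r}") from exc


def run_pipeline(
    tooth: np.ndarray,
    bone: Optional[np.ndarray],
    crown: Optional[np.ndarray],
    cfg: PipelineConfig = PipelineConfig(),
) -> LandmarkSet:
    """Locate all four landmarks from raw instance masks.

    The tooth mask may contain several instances (neighboring tooth
    fragments); only its largest is analyzed.  Bone and crown masks are
    each optional: a missing or empty one simply leaves the
    corresponding landmark pair absent, since the two locators are
    independent.
    """
    t = np.asarray(tooth)
    for other, name in ((bone, "bone"), (crown, "crown")):
        if other is not None and np.asarray(other).shape != t.shape:
            raise ShapeMismatchError(f"{name} mask shape differs from tooth mask")
    tooth_main = extract_main_instance(t, cfg.connectivity)
    h, w = tooth_main.shape

    alc_left = alc_right = cej_left = cej_right = None
    if bone is not None and np.any(bone):
        _, alc_left, alc_right = locate_alc(tooth_main, bone, cfg.alc_kernel)
    if crown is not None and np.any(crown):
        res = locate_cej(tooth_main, crown, cfg.cej)
        cej_left, cej_right = res.cej_left, res.cej_right

    return LandmarkSet(
        image_height=h,
        image_width=w,
        cej_left=cej_left,
        cej_right=cej_right,
        alc_left=alc_left,
        alc_right=alc_right,
    )
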