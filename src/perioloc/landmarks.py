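"""Named anatomical landmarks on a periapical radiograph.

Coordinate convention, used everywhere in this package including file
outputs: 0-based ``(row, col)``, origin at the top-left pixel, row
increasing apically (downward).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .errors import SchemaError

Point = Tuple[int, int]

#: Canonical landmark names, in reporting order.
LANDMARK_NAMES = ("cej_left", "cej_right", "alc_left", "alc_right")


@dataclass(frozen=True)
class LandmarkSet:
    """The four periodontal landmarks of one tooth.

    ``cej_left``/``cej_right`` mark the cemento-enamel junction on the
    mesial and distal tooth flanks; ``alc_left``/``alc_right`` mark the
    alveolar crest contacts.  Any point may be absent (``None``) when a
    locator could not determine it.  Image dimensions are carried so
    normalized coordinates can be computed from the set alone.
    """

    image_height: int
    image_width: int
    cej_left: Optional[Point] = None
    cej_right: Optional[Point] = None
    alc_left: Optional[Point] = None
    alc_right: Optional[Point] = None

    def __post_init__(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise SchemaError("image dimensions must be positive")
        for name in LANDMARK_NAMES:
            p = getattr(self, name)
            if p is None:
                continue
            r, c = p
            if not (0 <= r < self.image_height and 0 <= c < self.image_width):
                raise SchemaError(
                    f"landmark {name}={p!r} lies outside the "
                    f"{self.image_height}x{self.image_width} image"
                )
        for left, right in (("cej_left", "cej_right"), ("alc_left", "alc_right")):
            lp, rp = getattr(self, left), getattr(self, right)
            if lp is not None and rp is not None and lp[1] > rp[1]:
                raise SchemaError(
                    f"{left} column {lp[1]} exceeds {right} column {rp[1]}"
                )

    def points(self) -> dict:
        """Mapping of landmark name to point (present points only)."""
        return {
            name: getattr(self, name)
            for name in LANDMARK_NAMES
            if getattr(self, name) is not None
        }

    def to_dict(self) -> dict:
        d = {
            name: (list(getattr(self, name)) if getattr(self, name) is not None else None)
            for name in LANDMARK_NAMES
        }
        d["image_height"] = self.image_height
        d["image_width"] = self.image_width
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        try:
            h, w = int(d["image_height"]), int(d["image_width"])
        except KeyError as e:
            raise SchemaError(f"landmark set missing field {e.args[0]!r}") from e
        kwargs = {}
        for name in LANDMARK_NAMES:
            v = d.get(name)
            kwargs[name] = None if v is None else (int(v[0]), int(v[1]))
        return cls(image_height=h, image_width=w, **kwargs)
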