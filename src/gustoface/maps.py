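"""The key-landmark map: named index sets into the dense face mesh.

A dense face-mesh estimator emits several hundred indexed 3D points per
frame; the analysis uses a fixed subset outlining the brows, eyes, nose
tip and mouth (53 ids by default).  The map is data, not code: it ships
as an editable JSON file and can be replaced to match a different
estimator or region layout.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

from .errors import ValidationError

#: Regions that come in left/right pairs, in positional correspondence
#: (element j of the left tuple mirrors element j of the right tuple).
SIDED_REGIONS = (
    ("left_eyebrow", "right_eyebrow"),
    ("left_eye_contour", "right_eye_contour"),
    ("left_inner_eye_corner", "right_inner_eye_corner"),
    ("left_mouth_corner", "right_mouth_corner"),
)


@dataclass(frozen=True)
class LandmarkMap:
    """Named landmark-index sets for the analysed facial regions.

    Eyebrow tuples are ordered inner (medial) to outer; eye contours are
    ordered closed polygons.  Left/right follows the observer of the
    video, not the subject.
    """

    left_eyebrow: tuple[int, ...]
    right_eyebrow: tuple[int, ...]
    left_eye_contour: tuple[int, ...]
    right_eye_contour: tuple[int, ...]
    nose_tip: int
    left_inner_eye_corner: int
    right_inner_eye_corner: int
    left_mouth_corner: int
    right_mouth_corner: int
    upper_mid_lip: int
    lower_mid_lip: int

    def __post_init__(self) -> None:
        for name in ("left_eyebrow", "right_eyebrow"):
            if len(getattr(self, name)) != 5:
                raise ValidationError(f"{name} must have exactly 5 ids")
        for name in ("left_eye_contour", "right_eye_contour"):
            if len(getattr(self, name)) < 4:
                raise ValidationError(f"{name} must have at least 4 ids")
        if len(self.left_eye_contour) != len(self.right_eye_contour):
            raise ValidationError("eye contours must have equal length for mirror pairing")
        ids = self.all_ids()
        if len(ids) != len(set(ids)):
            raise ValidationError("landmark ids overlap between regions")

    # -- introspection -------------------------------------------------

    def regions(self) -> dict[str, tuple[int, ...]]:
        """All regions as name -> tuple of ids (singletons as 1-tuples)."""
        out: dict[str, tuple[int, ...]] = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = tuple(v) if isinstance(v, tuple) else (v,)
        return out

    def all_ids(self) -> tuple[int, ...]:
        """Union of all region ids, in region order (no duplicates expected)."""
        seen: list[int] = []
        for ids in self.regions().values():
            seen.extend(ids)
        return tuple(seen)

    def region_of(self, landmark_id: int) -> str:
        for name, ids in self.regions().items():
            if landmark_id in ids:
                return name
        raise KeyError(landmark_id)

    def mirror_pairs(self) -> dict[int, int]:
        """Id relabelling under reflection across the facial midline.

        Sided regions swap positionally; midline landmarks (nose tip,
        mid lips) map to themselves.
        """
        pairs: dict[int, int] = {self.nose_tip: self.nose_tip,
                                 self.upper_mid_lip: self.upper_mid_lip,
                                 self.lower_mid_lip: self.lower_mid_lip}
        for left_name, right_name in SIDED_REGIONS:
            left = self.regions()[left_name]
            right = self.regions()[right_name]
            for a, b in zip(left, right):
                pairs[a] = b
                pairs[b] = a
        return pairs

    # -- serialisation -------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkMap":
        kwargs = {}
        for f in fields(cls):
            if f.name not in d:
                raise ValidationError(f"landmark map missing region '{f.name}'")
            v = d[f.name]
            kwargs[f.name] = tuple(int(i) for i in v) if isinstance(v, (list, tuple)) else int(v)
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        d = {k: (list(v) if len(v) > 1 else v[0]) for k, v in self.regions().items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)
            fh.write("\n")


def default_map() -> LandmarkMap:
    """The packaged default 53-landmark map (see ``data/default_landmark_map.json``)."""
    text = resources.files("gustoface.data").joinpath("default_landmark_map.json").read_text()
    return LandmarkMap.from_dict(json.loads(text))
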