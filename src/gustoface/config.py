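"""Pipeline configuration: every analysis constant in one editable place.

Defaults are the reference analysis settings — α = 0.05, the stated
tree-ensemble hyperparameters, 5-frame display smoothing, the packaged
53-landmark map — so sensitivity analyses need a config change, not a
code change.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class ClassifierConfig:
    n_estimators: int = 200
    max_features: str = "sqrt"
    min_samples_split: int = 5
    min_samples_leaf: int = 2
    n_importance_seeds: int = 20

    def params(self) -> dict:
        return {"n_estimators": self.n_estimators, "max_features": self.max_features,
                "min_samples_split": self.min_samples_split,
                "min_samples_leaf": self.min_samples_leaf}


@dataclass
class PipelineConfig:
    landmark_map_path: str | None = None     # None -> packaged default map
    section: str = "SI+SII"
    coordinate_mode: str = "2d"
    smoothing_window: int = 5                # display only; stats stay unsmoothed
    sd_ddof: int = 1
    alpha: float = 0.05
    seed: int = 0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def __post_init__(self) -> None:
        if self.section not in ("SI", "SII", "SI+SII"):
            raise ValidationError(f"unknown section policy {self.section!r}")
        if self.coordinate_mode not in ("2d", "3d"):
            raise ValidationError(f"unknown coordinate mode {self.coordinate_mode!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValidationError("smoothing_window must be an odd integer >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        clf = ClassifierConfig(**raw.pop("classifier", {}))
        try:
            return cls(classifier=clf, **raw)
        except TypeError as e:
            raise ValidationError(f"{path}: unknown config key ({e})") from e

    def to_dict(self) -> dict:
        return asdict(self)

    def landmark_map(self):
        from .maps import LandmarkMap, default_map
        if self.landmark_map_path is None:
            return default_map()
        return LandmarkMap.from_json(self.landmark_map_path)
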