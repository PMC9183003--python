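"""Run configuration: one YAML/JSON-mappable object covering every stage."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classify import ClassifierSpec
from .constants import OpticalConstants
from .features import FeatureDefinitionSet
from .hemodynamics import ReferenceIntervalPolicy
from .preprocess import FilterSpec, WindowingSpec
from .simulate import SubjectSimSpec


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    ``mode`` is ``synthetic`` (generate a cohort) or ``files`` (read the
    recordings listed in ``paths``).  The master ``seed`` drives cohort
    generation and derives each subject's classifier seed.
    """

    mode: str = "synthetic"
    paths: tuple[str, ...] = ()
    n_subjects: int = 10
    effect_range: tuple[float, ...] = (1.0,)
    seed: int = 0
    out_dir: str = "nirsfatigue_out"
    n_folds: int = 10
    constants: OpticalConstants = field(default_factory=OpticalConstants)
    reference: ReferenceIntervalPolicy = field(default_factory=ReferenceIntervalPolicy)
    filter: FilterSpec = field(default_factory=FilterSpec)
    windowing: WindowingSpec = field(default_factory=WindowingSpec)
    features: FeatureDefinitionSet = field(default_factory=FeatureDefinitionSet)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    synthetic: SubjectSimSpec = field(default_factory=SubjectSimSpec)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "files" and not self.paths:
            raise ValueError("files mode requires at least one input path")
        self.paths = tuple(self.paths)
        self.effect_range = tuple(float(e) for e in self.effect_range)

    _SECTIONS = {
        "constants": OpticalConstants,
        "reference": ReferenceIntervalPolicy,
        "filter": FilterSpec,
        "windowing": WindowingSpec,
        "features": FeatureDefinitionSet,
        "classifier": ClassifierSpec,
        "synthetic": SubjectSimSpec,
    }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key, typ in cls._SECTIONS.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                section = dict(kwargs[key])
                if key == "synthetic" and "sites" in section:
                    section["sites"] = tuple(section["sites"])
                kwargs[key] = typ(**section)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        def _plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [_plain(v) for v in obj]
            return obj

        out = {k: _plain(getattr(self, k)) for k in (
            "mode", "paths", "n_subjects", "effect_range", "seed", "out_dir", "n_folds"
        )}
        out.update({k: _plain(getattr(self, k)) for k in self._SECTIONS})
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


__all__ = ["RunConfig"]
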