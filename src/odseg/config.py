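"""Pipeline configuration: nested stage configs, dataset prior profiles,
YAML loading with strict key validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError
from .localize import LocalizationConfig
from .segment import SelectionConfig
from .vessels import LineDetectorConfig


@dataclass
class DehazeConfig:
    enabled: bool = True
    n_directions: int = 500
    lam: float = 0.1
    t_floor: float = 0.1

    def validate(self) -> None:
        if self.n_directions < 2:
            raise ParameterError("dehaze.n_directions must be >= 2")
        if self.lam < 0:
            raise ParameterError("dehaze.lam must be >= 0")
        if not (0 < self.t_floor <= 1):
            raise ParameterError("dehaze.t_floor must be in (0, 1]")


# Dataset prior profiles: average OD radius R_a and area A_a at the 605 px
# working scale.  The synthetic profile matches the scene generator; the
# named public-database profiles ship a nominal 40 px prior that users
# should override with values measured from their ground truth.
_NOMINAL = {"avg_radius": 40.0, "avg_area": float(np.pi * 40.0**2)}
PROFILES: dict[str, dict[str, float]] = {
    "synthetic": dict(_NOMINAL),
    "drions": dict(_NOMINAL),
    "messidor": dict(_NOMINAL),
    "onhsd": dict(_NOMINAL),
    "diaretdb1": dict(_NOMINAL),
    "drishti": dict(_NOMINAL),
    "rimone": dict(_NOMINAL),
}

# Working scale: images whose short side greatly exceeds this are rescaled
# so the short side maps here before processing, keeping the fixed 300 px
# crop and pixel priors meaningful across camera resolutions.
WORKING_SCALE = 605


@dataclass
class PipelineConfig:
    dataset_profile: str = "synthetic"
    seed: int = 0
    debug_dir: str | None = None
    dehaze: DehazeConfig = field(default_factory=DehazeConfig)
    localize: LocalizationConfig = field(default_factory=LocalizationConfig)
    vessels: LineDetectorConfig = field(default_factory=LineDetectorConfig)
    segment: SelectionConfig = field(default_factory=SelectionConfig)

    def __post_init__(self) -> None:
        if self.dataset_profile not in PROFILES:
            raise ParameterError(
                f"unknown dataset_profile {self.dataset_profile!r}; "
                f"known: {sorted(PROFILES)}"
            )

    def validate(self) -> None:
        self.dehaze.validate()
        self.localize.validate()
        self.vessels.validate()
        self.segment.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build a config from a nested dict, rejecting unknown keys."""
        data = dict(data or {})
        explicit_radius = "avg_radius" in (data.get("localize") or {})
        explicit_area = "avg_area" in (data.get("segment") or {})
        kwargs = {}
        sub = {
            "dehaze": DehazeConfig,
            "localize": LocalizationConfig,
            "vessels": LineDetectorConfig,
            "segment": SelectionConfig,
        }
        for name, klass in sub.items():
            if name in data:
                payload = data.pop(name)
                known = {f.name for f in dataclasses.fields(klass)}
                bad = set(payload) - known
                if bad:
                    raise ParameterError(f"unknown {name} config keys: {sorted(bad)}")
                if name == "vessels" and "line_lengths" in payload:
                    payload["line_lengths"] = tuple(payload["line_lengths"])
                kwargs[name] = klass(**payload)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ParameterError(f"unknown config keys: {sorted(bad)}")
        kwargs.update(data)
        cfg = cls(**kwargs)
        # apply the dataset profile priors unless explicitly overridden
        prior = PROFILES[cfg.dataset_profile]
        if not explicit_radius:
            cfg.localize.avg_radius = prior["avg_radius"]
        if not explicit_area:
            cfg.segment.avg_area = prior["avg_area"]
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})
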