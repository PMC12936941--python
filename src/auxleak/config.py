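"""Run configuration: defaults, validation and YAML round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .simulate import SyntheticConfig


@dataclass(frozen=True)
class FilterConfig:
    max_rel_length_change: float = 0.15
    min_frames: int = 5
    min_r2: float = 0.8

    def __post_init__(self) -> None:
        if self.max_rel_length_change <= 0 or self.min_r2 <= 0:
            raise ValueError("filter thresholds must be strictly positive")
        if self.min_frames < 2:
            raise ValueError("min_frames must be at least 2")


@dataclass(frozen=True)
class ModelConfig:
    k_m: float = 1.0
    epsilon: float = 1.0
    i_c_factor: float = 20.0
    mu_wt: float = 0.70
    mu_max_aux: float = 0.90

    def __post_init__(self) -> None:
        for name in ("k_m", "epsilon", "i_c_factor", "mu_wt", "mu_max_aux"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    seed: int = 0
    frame_interval_min: float = 5.0
    neighborhood_radii_um: tuple[float, ...] = (5.0, 9.0, 13.0)
    n_permutations: int = 10_000
    filters: FilterConfig = field(default_factory=FilterConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be strictly positive")
        if any(r <= 0 for r in self.neighborhood_radii_um):
            raise ValueError("neighborhood radii must be strictly positive")
        object.__setattr__(self, "neighborhood_radii_um", tuple(self.neighborhood_radii_um))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["neighborhood_radii_um"] = list(self.neighborhood_radii_um)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "filters" in d and isinstance(d["filters"], dict):
            d["filters"] = FilterConfig(**d["filters"])
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelConfig(**d["model"])
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
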