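"""Run configuration: one YAML-serializable object covering the whole bench.

A :class:`RunConfig` captures everything a simulate → fit → recommend run
depends on — subsampling strides, cadence protocol, trial duration, noise
conditions, regression orders and CV folds, composite weight, tolerance,
and the master seed — and round-trips losslessly through YAML so a run
log can record the full resolved configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .stepper import DEFAULT_NOISE, NoiseSpec


@dataclass
class RunConfig:
    strides: tuple[int, int, int] = (2, 4, 5)
    cadences: str | list[int] = "low-high"
    duration_s: float = 2700.0            # the bench's 45 min trials
    noise: NoiseSpec = field(default_factory=lambda: DEFAULT_NOISE)
    degrees: tuple[int, ...] = (1, 2, 3, 4, 5)
    cv_folds: int = 10
    overfit_bound: float = 0.05
    w: float = 0.5
    tolerance: float = 0.10
    top_n: int = 10
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not (0.0 <= self.w <= 1.0):
            raise ValueError("w must lie in [0, 1]")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if isinstance(self.cadences, str) and self.cadences != "low-high":
            raise ValueError("cadences must be a list of integers or 'low-high'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["strides"] = list(self.strides)
        d["degrees"] = list(self.degrees)
        if not isinstance(self.cadences, str):
            d["cadences"] = list(self.cadences)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseSpec(**d["noise"])
        if "strides" in d:
            d["strides"] = tuple(d["strides"])
        if "degrees" in d:
            d["degrees"] = tuple(d["degrees"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config YAML must be a mapping")
        return cls.from_dict(data)
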