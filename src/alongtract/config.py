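"""Run configuration: every tunable with its study default, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline tunables.

    Defaults are the study conditions: 30 segments with 20 % overlap,
    FA gate 0.2, tract-probability threshold 5e-5, 2 mm cleaning
    kernel, 10,000 permutations, 100,000 accumulator simulations, 100
    initial candidates x 20 simplex repeats, RT quantiles
    (.1,.3,.5,.7,.9), retention bounds 150-1500 ms.
    """

    n_segments: int = 30
    overlap: float = 0.2
    fa_thresh: float = 0.2
    prob_thresh: float = 5e-5
    dilate_mm: float = 2.0
    clip_fractions: tuple[float, float] = (0.1, 0.9)
    n_perm: int = 10_000
    n_sim: int = 100_000
    n_init: int = 100
    n_repeats: int = 20
    quantiles: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    rt_bounds_ms: tuple[float, float] = (150.0, 1500.0)
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_n_steps: int = 100
    skeleton_samples: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if not 0 <= self.clip_fractions[0] < self.clip_fractions[1] <= 1:
            raise ValueError("clip_fractions must satisfy 0 <= lo < hi <= 1")
        for name in ("fa_thresh", "prob_thresh", "dilate_mm", "tfce_E", "tfce_H"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if list(self.quantiles) != sorted(set(self.quantiles)):
            raise ValueError("quantiles must be strictly increasing")
        if not self.rt_bounds_ms[0] < self.rt_bounds_ms[1]:
            raise ValueError("rt_bounds_ms must be ordered")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("clip_fractions", "quantiles", "rt_bounds_ms"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        for key in ("clip_fractions", "quantiles", "rt_bounds_ms"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
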