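"""Run configuration shared by training, inference and evaluation.

Every tunable the method leaves open lives here so that reports can embed the
exact configuration used and reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import yaml

from cav.core import round_half_up
from cav.errors import FormatError


@dataclasses.dataclass
class RunConfig:
    # Windowing
    sizes_s: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    increments: tuple[float, ...] = (0.0, 0.25, 0.5)
    base_len: Optional[int] = None  # None -> round(min(sizes_s) * frame_rate)

    # Clustering
    k_activity: Optional[int] = None  # None -> ceil(sqrt(n_windows / 2))
    k_dictionary: Optional[int] = None  # None -> ceil(k2_fraction * n_centers)
    k2_fraction: float = 0.75
    kmeans_n_init: int = 10
    prune_min_members: int = 6

    # Representation
    alpha: float = 0.5  # Laplace smoothing for transition/init probabilities
    stop_fraction: float = 0.05

    # Observation encoding
    tau: float = 1.0  # match when distance <= tau * entry radius
    step_fraction: float = 0.25
    empty_observation_policy: str = "fallback"  # or "strict"

    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sizes_s or any(s <= 0 for s in self.sizes_s):
            raise FormatError("sizes_s must be positive")
        if any(not 0 <= f < 1 for f in self.increments):
            raise FormatError("increments must lie in [0, 1)")
        if self.base_len is not None and self.base_len < 1:
            raise FormatError("base_len must be >= 1")
        if not 0 <= self.stop_fraction < 1:
            raise FormatError("stop_fraction must lie in [0, 1)")
        if self.alpha <= 0:
            raise FormatError("alpha must be > 0")
        if self.tau < 0:
            raise FormatError("tau must be >= 0")
        if not 0 < self.step_fraction <= 1:
            raise FormatError("step_fraction must lie in (0, 1]")
        if self.empty_observation_policy not in ("fallback", "strict"):
            raise FormatError("empty_observation_policy must be 'fallback' or 'strict'")
        self.sizes_s = tuple(sorted(float(s) for s in self.sizes_s))
        self.increments = tuple(float(f) for f in self.increments)

    # -- derived quantities -------------------------------------------------

    def resolve_base_len(self, frame_rate: float) -> int:
        if self.base_len is not None:
            return self.base_len
        return max(1, round_half_up(min(self.sizes_s) * frame_rate))

    def k_for_activity(self, n_windows: int) -> int:
        if self.k_activity is not None:
            return self.k_activity
        return max(1, math.ceil(math.sqrt(n_windows / 2)))

    def k_for_dictionary(self, n_centers: int) -> int:
        if self.k_dictionary is not None:
            return self.k_dictionary
        return max(1, math.ceil(self.k2_fraction * n_centers))

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sizes_s"] = list(self.sizes_s)
        d["increments"] = list(self.increments)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("sizes_s", "increments"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a mapping")
        return cls.from_dict(data)
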