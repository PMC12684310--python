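"""Run configuration: filter thresholds and genome-scale constants.

Defaults follow the study design this package supports: a crane-like
genome with a 3.42 cM/Mb sex-averaged recombination rate and a 13-year
generation time; per-genotype depth window 4-50 with genotype quality
>= 30; site-level genotyping rate >= 40%.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml


@dataclass
class RunConfig:
    seed: int | None = None
    bin_size: int = 1_000_000
    alpha: float = 0.05
    recombination_rate: float = 3.42  # cM/Mb
    generation_time: float = 13.0  # years
    depth_min: int = 4
    depth_max: int = 50
    gq_min: int = 30
    genotyping_rate: float = 0.4
    # stricter per-genotype depth window applied to load-analysis sites
    load_depth_min: int = 5
    load_depth_max_modern: int = 20
    load_depth_max_historical: int = 16

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "seed":
                continue
            value = getattr(self, f.name)
            if value < 0:
                raise ValueError(f"{f.name} must be non-negative, got {value}")
        if not 0 <= self.genotyping_rate <= 1:
            raise ValueError("genotyping_rate must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def require_seed(self) -> int:
        """Return the seed, failing loudly for unseeded stochastic runs."""
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic operations")
        return int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
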