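"""Run configuration: every pipeline tunable with validated defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .types import IslandClockError
from .ga import GAConfig
from .simulate import SimulationTruth


@dataclass
class RunConfig:
    """All pipeline tunables; defaults follow the published recipe."""

    seed: int = 0
    split_fraction: float = 0.7
    split_by_dataset: bool = True
    prefilter_threshold: float = 0.3
    prefilter_rule: str = "max"
    detection_p_threshold: float = 0.01
    knn_k: int = 10
    en_alpha: float = 0.5
    cv_folds: int = 10
    adult_age: float = 20.0
    baseline_iterations: int = 2500
    baseline_n_cpgs: int = 350
    power_target: float = 0.80
    power_alpha: float = 0.05
    ga: GAConfig = field(default_factory=GAConfig)
    simulation: SimulationTruth = field(default_factory=SimulationTruth)

    def validate(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise IslandClockError("split_fraction must lie in (0, 1)")
        if not 0 <= self.prefilter_threshold <= 1:
            raise IslandClockError("prefilter_threshold must lie in [0, 1]")
        if self.prefilter_rule not in ("max", "mean", "pooled"):
            raise IslandClockError("prefilter_rule must be 'max', 'mean' or 'pooled'")
        if not 0 < self.en_alpha <= 1:
            raise IslandClockError("en_alpha must lie in (0, 1]")
        if self.cv_folds < 2:
            raise IslandClockError("cv_folds must be >= 2")
        if not 0 < self.power_target < 1 or not 0 < self.power_alpha < 1:
            raise IslandClockError("power_target and power_alpha must lie in (0, 1)")
        if self.baseline_iterations < 1 or self.baseline_n_cpgs < 1:
            raise IslandClockError("baseline settings must be positive")
        self.ga.validate()
        self.simulation.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        ga_raw = raw.pop("ga", {})
        sim_raw = raw.pop("simulation", {})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise IslandClockError(f"unknown config keys: {sorted(unknown)}")
        ga_known = set(GAConfig.__dataclass_fields__)
        sim_known = set(SimulationTruth.__dataclass_fields__)
        bad = set(ga_raw) - ga_known
        if bad:
            raise IslandClockError(f"unknown ga config keys: {sorted(bad)}")
        bad = set(sim_raw) - sim_known
        if bad:
            raise IslandClockError(f"unknown simulation config keys: {sorted(bad)}")
        if "ridge_lambda_grid" in ga_raw:
            ga_raw["ridge_lambda_grid"] = np.asarray(ga_raw["ridge_lambda_grid"], dtype=float)
        if "tissue_sizes" in sim_raw:
            sim_raw["tissue_sizes"] = {str(k): int(v) for k, v in sim_raw["tissue_sizes"].items()}
        if "age_ranges" in sim_raw:
            sim_raw["age_ranges"] = {str(k): tuple(map(float, v)) for k, v in sim_raw["age_ranges"].items()}
        cfg = cls(ga=GAConfig(**ga_raw), simulation=SimulationTruth(**sim_raw), **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ga"]["ridge_lambda_grid"] = list(map(float, self.ga.ridge_lambda_grid))
        d["simulation"] = self.simulation.to_dict()
        return d
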