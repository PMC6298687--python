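"""Experiment configuration: schema, serialization, hashing.

A single YAML document describes an experiment end to end (model state,
estimator design, parameter bounds, acquisition settings, evaluation
protocol, benchmark sizes, root seed).  The schema is validated by
pydantic, round-trips losslessly through YAML, and hashes stably so output
files can be traced back to the exact configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .neuromass import SimParams, load_defaults, tune_defaults

__all__ = ["ExperimentConfig", "load_config", "config_hash"]

_DEF = load_defaults()


class SimBlock(BaseModel):
    state: Literal["DD", "naive"] = "DD"
    overrides: dict[str, float] = Field(default_factory=dict)


class SwiftBlock(BaseModel):
    f0: float = float(_DEF["swift"]["f0"])
    tau_slow: float = float(_DEF["swift"]["tau_slow"])
    fast_ratio: float = float(_DEF["swift"]["fast_ratio"])


class BoundsBlock(BaseModel):
    phase: tuple[float, float]
    threshold: tuple[float, float]
    amplitude: tuple[float, float]

    @field_validator("amplitude")
    @classmethod
    def _amp_nonneg(cls, v):
        if v[0] < 0:
            raise ValueError("amplitude lower bound must be non-negative")
        return v


class AcquisitionBlock(BaseModel):
    nu: float = 0.25
    delta: float = 0.1


class EvaluationBlock(BaseModel):
    settle: float = float(_DEF["evaluation"]["settle"])
    window: float = float(_DEF["evaluation"]["window"])
    full_protocol: bool = False  # switch to the 10 s + 10 s protocol

    def timings(self) -> tuple[float, float]:
        if self.full_protocol:
            return (
                float(_DEF["evaluation"]["settle_full"]),
                float(_DEF["evaluation"]["window_full"]),
            )
        return self.settle, self.window


class AdcBlock(BaseModel):
    active: tuple[str, ...] = ("phase",)
    budget: int = 25
    n_init: int = 3


class BenchmarkBlock(BaseModel):
    active: tuple[str, ...] = ("phase", "threshold", "amplitude")
    trials: int = 50
    budget: int = 100
    resolution: int = 16
    sigma_grid: tuple[float, ...] = (0.0, 1.0, 2.0)
    snr_trials: int = 20


class ExperimentConfig(BaseModel):
    sim: SimBlock = Field(default_factory=SimBlock)
    swift: SwiftBlock = Field(default_factory=SwiftBlock)
    bounds: BoundsBlock
    acquisition: AcquisitionBlock = Field(default_factory=AcquisitionBlock)
    evaluation: EvaluationBlock = Field(default_factory=EvaluationBlock)
    adc: AdcBlock = Field(default_factory=AdcBlock)
    benchmark: BenchmarkBlock = Field(default_factory=BenchmarkBlock)
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def default(cls) -> "ExperimentConfig":
        b = _DEF["bounds"]
        return cls(
            bounds=BoundsBlock(
                phase=tuple(b["phase"]),
                threshold=tuple(b["threshold"]),
                amplitude=tuple(b["amplitude"]),
            )
        )

    def sim_params(self) -> SimParams:
        base = tune_defaults(self.sim.state)
        if self.sim.overrides:
            from dataclasses import replace

            base = replace(base, **self.sim.overrides)
        return base

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            data = yaml.safe_load(f)
        return cls.model_validate(data)


def load_config(path: Optional[str]) -> ExperimentConfig:
    if path is None:
        return ExperimentConfig.default()
    return ExperimentConfig.from_yaml(path)


def config_hash(cfg: ExperimentConfig) -> str:
    """Stable short hash of the canonical JSON form."""
    blob = json.dumps(cfg.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
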