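"""Run configuration: defaults, validation, (de)serialization.

A flat YAML/JSON mapping fully determines a run.  Rates default to the
standard parameterization (beta = (43 s)^-1, delta = (14 min)^-1,
phi = 2.67, F = 0.9); alpha and gamma are normally derived by
calibration but can be overridden explicitly.  Giving ``alpha_per_min``
without ``gamma_per_min`` switches to the fixed-alpha pool calibration
(gamma = delta*(S*phi - beta/alpha)).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import yaml

from . import params as mp
from .params import RateConstants

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    beta_per_min: float = mp.DEFAULT_BETA
    delta_per_min: float = mp.DEFAULT_DELTA
    target_F: float = 0.9
    target_phi: float = mp.DEFAULT_PHI
    slots: List[float] = field(default_factory=lambda: [40.0, 60.0, 80.0])
    alpha_per_min: Optional[float] = None
    gamma_per_min: Optional[float] = None
    # integration settings
    dt: float = 0.005
    t_end: float = 30.0
    sample_every: float = 0.05
    # stochastic settings
    seed: int = 0
    n_runs: int = 10
    sample_dt_s: float = 1.0
    burn_in_min: float = 2.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.target_F < 1.0:
            raise ValueError(f"target_F must be in (0, 1), got {self.target_F}")
        if self.target_phi <= 0:
            raise ValueError("target_phi must be positive")
        if self.beta_per_min < 0 or self.delta_per_min < 0:
            raise ValueError("rates must be non-negative")
        if not self.slots or any(s < 0 for s in self.slots):
            raise ValueError("slots must be a non-empty list of non-negative numbers")
        if self.dt <= 0 or self.t_end <= 0 or self.sample_every <= 0:
            raise ValueError("dt, t_end and sample_every must be positive")
        if self.n_runs < 1 or self.sample_dt_s <= 0 or self.burn_in_min < 0:
            raise ValueError("invalid stochastic settings")

    @property
    def S(self) -> float:
        return float(sum(self.slots))

    def rates(self) -> RateConstants:
        """Resolve the four rates, applying calibration where needed."""
        beta, delta = self.beta_per_min, self.delta_per_min
        if self.alpha_per_min is not None and self.gamma_per_min is not None:
            return RateConstants(self.alpha_per_min, beta, self.gamma_per_min, delta)
        if self.alpha_per_min is not None:
            return RateConstants.with_fixed_alpha(
                self.target_phi, self.S, self.alpha_per_min, beta=beta, delta=delta
            )
        gamma = (
            self.gamma_per_min
            if self.gamma_per_min is not None
            else mp.calibrate_gamma(self.target_F, self.target_phi, self.S, delta)
        )
        alpha = mp.calibrate_alpha(self.target_F, self.target_phi, self.S, beta)
        return RateConstants(alpha, beta, gamma, delta)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Load and validate a YAML (JSON-compatible) config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash identifying a configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]
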