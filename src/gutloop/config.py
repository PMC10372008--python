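"""Simulation configuration: defaults, validation, and file loading.

Defaults follow the model's standard operating point: step scale
sigma = 1e-4 (exponential mean during addiction/withdrawal), addiction
length tau = 20000 steps, maximal severity R = 0.7, inflow mu = 1e-8,
intra-strain competition s = 1, growth function alpha = 3 / beta = 0.1,
trend windows omega = 10, and a 100000-step withdrawal horizon.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError
from .dynamics import INFLOW_MODES
from .feedback import FEEDBACK_VARIANTS

__all__ = ["SimConfig", "load_config"]


@dataclass
class SimConfig:
    # community
    n_strains: int = 50
    dims: int = 2
    mean_effect: float = 10.0
    affecting_fraction: float = 1.0
    cost: float = 0.0
    behavior_independent_fraction: float = 0.0
    behavior_independent_rate: float = 0.6
    # behavior schedule
    sigma: float = 1e-4
    tau: int = 20000
    R: float = 0.7
    withdrawal_horizon: int = 100000
    total_steps_two_strain: int = 100000
    intervention_new_strains: int = 0
    # dynamics
    s: float = 1.0
    mu: float = 1e-8
    delta: float = 0.5
    alpha: float = 3.0
    beta: float = 0.1
    growth_floor: float = 0.1
    dynamics_variant: str = "normalized"
    inflow_mode: str = "per_strain_scaled"
    divergence_ceiling: float = 1e6
    # feedback
    omega_m: int = 10
    omega_h: int = 10
    slope_tol: float = 1e-6
    feedback_variant: str = "reward_circuit"
    # equilibration and metrics
    stabilization_tol: float = 1e-10
    stabilization_window: int = 100
    stabilization_cap: int = 10000
    clamp_at_R: bool = True
    return_epsilon: float = 0.01
    # bookkeeping
    thin: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        def req(cond: bool, field: str, constraint: str) -> None:
            if not cond:
                raise ConfigError(
                    f"invalid value for '{field}': {getattr(self, field)!r} ({constraint})"
                )

        req(self.n_strains >= 1, "n_strains", "must be >= 1")
        req(self.dims >= 1, "dims", "must be >= 1")
        req(self.mean_effect >= 0, "mean_effect", "must be >= 0")
        req(0 <= self.affecting_fraction <= 1, "affecting_fraction", "must be in [0, 1]")
        req(self.cost >= 0, "cost", "must be >= 0")
        req(0 <= self.behavior_independent_fraction <= 1,
            "behavior_independent_fraction", "must be in [0, 1]")
        req(self.sigma > 0, "sigma", "must be > 0")
        req(self.tau >= 0, "tau", "must be >= 0")
        req(0 < self.R <= 1, "R", "must satisfy 0 < R <= 1")
        req(self.withdrawal_horizon >= 1, "withdrawal_horizon", "must be >= 1")
        req(self.total_steps_two_strain >= 1, "total_steps_two_strain", "must be >= 1")
        req(self.intervention_new_strains >= 0, "intervention_new_strains", "must be >= 0")
        req(self.s >= 0, "s", "must be >= 0")
        req(self.mu >= 0, "mu", "must be >= 0")
        req(self.delta >= 0, "delta", "must be >= 0")
        req(self.alpha > 0, "alpha", "must be > 0")
        req(self.beta >= 0, "beta", "must be >= 0")
        req(self.dynamics_variant in ("normalized", "glv"),
            "dynamics_variant", "must be 'normalized' or 'glv'")
        req(self.inflow_mode in INFLOW_MODES, "inflow_mode", f"must be one of {INFLOW_MODES}")
        req(self.feedback_variant in FEEDBACK_VARIANTS,
            "feedback_variant", f"must be one of {FEEDBACK_VARIANTS}")
        req(self.omega_m >= 2, "omega_m", "must be >= 2")
        req(self.omega_h >= 2, "omega_h", "must be >= 2")
        req(self.slope_tol > 0, "slope_tol", "must be > 0")
        req(self.stabilization_tol > 0, "stabilization_tol", "must be > 0")
        req(self.stabilization_window >= 1, "stabilization_window", "must be >= 1")
        req(self.stabilization_cap >= 0, "stabilization_cap", "must be >= 0")
        req(self.return_epsilon > 0, "return_epsilon", "must be > 0")
        req(self.thin >= 1, "thin", "must be >= 1")

    def replace(self, **overrides) -> "SimConfig":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML/JSON file plus overrides.

    Unknown keys are rejected; an empty (or absent) file yields all defaults;
    overrides take precedence over file values.
    """
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        values.update(raw)
    if overrides:
        values.update(overrides)
    unknown = sorted(set(values) - _FIELDS)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    return SimConfig(**values)
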