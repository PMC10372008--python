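"""Microbiome-to-host feedback: trend indicators and the behavioral effect.

Strains sense whether their own population is growing or declining over a
rolling window of ``omega_m`` time points (the OLS slope of their proportion
against time) and secrete reward- or aversion-like signals accordingly.  The
host likewise carries a trend over its last ``omega_h`` behavior values.  A
strain whose signal aligns with the host's current trend reinforces it; a
strain signalling decline reverses it.  The aggregate effect is

    M(t) = |sigma(t)| * I_b(t) * sum_i x_i(t) * d_i * I_m_i(t)

where ``I_b`` and ``I_m_i`` are the sign indicators of the host and strain
slopes (with a neutrality band of +/- 1e-6), ``x_i`` the strain's relative
abundance, ``d_i`` its effect magnitude, and ``sigma(t)`` the baseline step
magnitude of that time point.  The host then moves by the baseline step plus
M, clamped to its allowed segment.

A second, *direct-pull* variant skips the trend logic: each strain pulls the
host straight toward its own feature coordinates, weighted by abundance and
effect magnitude, and only the component along the behavior axis acts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, WindowError
from .strains import StrainSet

__all__ = [
    "FeedbackParams",
    "BehaviorState",
    "window_slope",
    "trend_indicator",
    "microbiome_effect",
    "direct_pull_effect",
    "behavior_update",
    "compute_all_indicators",
]

FEEDBACK_VARIANTS = ("reward_circuit", "direct_pull")

#: below this separation a strain sitting on top of the host contributes no pull
_PULL_EPS = 1e-12


@dataclass
class FeedbackParams:
    omega_m: int = 10
    omega_h: int = 10
    slope_tol: float = 1e-6
    variant: str = "reward_circuit"

    def __post_init__(self) -> None:
        if self.omega_m < 2 or self.omega_h < 2:
            raise ParameterError("window lengths omega_m/omega_h must be >= 2")
        if not self.slope_tol > 0:
            raise ParameterError("slope_tol must be > 0")
        if self.variant not in FEEDBACK_VARIANTS:
            raise ParameterError(f"variant must be one of {FEEDBACK_VARIANTS}")


@dataclass
class BehaviorState:
    """Host behavior coordinate (first component active) with history."""

    b: np.ndarray
    history: list
    phase: str = "equilibrium"

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float).reshape(-1)

    @property
    def b1(self) -> float:
        return float(self.b[0])


def window_slope(series) -> float:
    """OLS slope of equally spaced values against their time index."""
    x = np.asarray(series, dtype=float).reshape(-1)
    w = x.size
    if w < 2:
        raise WindowError(f"window needs >= 2 points, got {w}")
    t = np.arange(w, dtype=float)
    tc = t - t.mean()
    return float(tc @ (x - x.mean()) / (tc @ tc))


def trend_indicator(slope: float, tol: float) -> int:
    """Sign of a trend with a neutrality band: +1, -1, or 0 (strict at +/-tol)."""
    if slope > tol:
        return 1
    if slope < -tol:
        return -1
    return 0


def microbiome_effect(
    x: np.ndarray,
    strains: StrainSet,
    I_m: np.ndarray,
    I_b: int,
    sigma_step: float,
) -> float:
    """Aggregate reward-circuit effect M(t) = |sigma| * I_b * sum x_i d_i I_m_i."""
    x = np.asarray(x, dtype=float).reshape(-1)
    I_m = np.asarray(I_m).reshape(-1)
    return float(abs(sigma_step) * I_b * np.sum(x * strains.effect_magnitude * I_m))


def direct_pull_effect(
    b: np.ndarray,
    strains: StrainSet,
    x: np.ndarray,
    sigma_step: float,
) -> float:
    """Direct-pull effect: abundance- and d-weighted unit pulls toward each
    strain, projected on the behavior axis.  Strains within 1e-12 of the host
    contribute nothing (their direction is undefined)."""
    b = np.asarray(b, dtype=float).reshape(-1)
    x = np.asarray(x, dtype=float).reshape(-1)
    diff = strains.features - b
    norm = np.linalg.norm(diff, axis=1)
    ok = norm >= _PULL_EPS
    acc = np.sum(x[ok] * strains.effect_magnitude[ok] * diff[ok, 0] / norm[ok])
    return float(abs(sigma_step) * acc)


def behavior_update(
    b1: float, base_step: float, M: float, lower: float, upper: float
) -> float:
    """New behavior coordinate: b1 + base step + M, clamped to [lower, upper]."""
    if lower > upper:
        raise ParameterError(f"lower {lower} exceeds upper {upper}")
    return float(min(max(b1 + (base_step + M), lower), upper))


def compute_all_indicators(
    micro_history,
    behavior_history,
    params: FeedbackParams,
    n_strains: int | None = None,
):
    """Per-strain and host trend indicators from rolling histories.

    Histories shorter than their window yield indicator 0 (warm-up).
    ``micro_history`` is a sequence of proportion vectors (newest last);
    ``behavior_history`` a sequence of b1 values.  ``n_strains`` sizes the
    warm-up indicator vector when the history is still empty.
    """
    micro_history = list(micro_history)
    behavior_history = list(behavior_history)
    if micro_history:
        n = np.asarray(micro_history[-1]).size
    else:
        n = 0 if n_strains is None else n_strains
    if len(micro_history) < params.omega_m:
        I_m = np.zeros(n, dtype=int)
    else:
        window = np.asarray(micro_history[-params.omega_m:], dtype=float)
        t = np.arange(params.omega_m, dtype=float)
        tc = t - t.mean()
        slopes = tc @ (window - window.mean(axis=0)) / (tc @ tc)
        I_m = np.array([trend_indicator(s, params.slope_tol) for s in slopes])
    if len(behavior_history) < params.omega_h:
        I_b = 0
    else:
        I_b = trend_indicator(
            window_slope(behavior_history[-params.omega_h:]), params.slope_tol
        )
    return I_m, I_b
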