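"""One-step propagation of the microbiome composition.

Two variants are provided.  The *normalized* model tracks relative
abundances: a forward-Euler logistic-with-cost update per strain,

    x_i(t+1) = x_i(t) + x_i(t) * (r_i(t) - s * x_i(t) - c_i)

followed by normalization to sum 1, a small immigration inflow, and a second
normalization.  The double normalization holds the community at carrying
capacity, so strains compete for a fixed resource pool; the inflow keeps
every strain above zero so no strain ever goes permanently extinct.

The *generalized Lotka-Volterra* (GLV) variant tracks absolute abundances
with an interaction matrix A (diagonal -1, off-diagonals -delta) and no
normalization:

    x_i(t+1) = x_i(t) + x_i(t) * (r_i(t) + A_i . x(t)) + mu/N

These functions are the single-step reference implementations; the scenario
runners use compiled loops that a dedicated test holds equal to compositions
of these steps.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateCommunityError, InstabilityError, ParameterError
from .strains import StrainSet

__all__ = [
    "DynamicsParams",
    "MicrobiomeState",
    "InteractionMatrix",
    "build_interaction_matrix",
    "step_normalized",
    "step_glv",
    "uniform_state",
]

INFLOW_MODES = ("per_strain_scaled", "per_strain_constant", "none")


@dataclass
class DynamicsParams:
    """Competition parameters.

    ``s``: intra-strain (self-limitation) competition coefficient, shared by
    all strains.  ``mu``: total immigration inflow; in ``per_strain_scaled``
    mode each strain receives mu/N, in ``per_strain_constant`` each receives
    mu regardless of N, and ``none`` disables inflow.  ``delta``: magnitude
    of the GLV off-diagonal competition.
    """

    s: float = 1.0
    mu: float = 1e-8
    delta: float = 0.5
    inflow_mode: str = "per_strain_scaled"
    variant: str = "normalized"
    divergence_ceiling: float = 1e6

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ParameterError(f"s must be >= 0, got {self.s}")
        if self.mu < 0:
            raise ParameterError(f"mu must be >= 0, got {self.mu}")
        if self.delta < 0:
            raise ParameterError(f"delta must be >= 0, got {self.delta}")
        if self.inflow_mode not in INFLOW_MODES:
            raise ParameterError(f"inflow_mode must be one of {INFLOW_MODES}")
        if self.variant not in ("normalized", "glv"):
            raise ParameterError("variant must be 'normalized' or 'glv'")


@dataclass
class MicrobiomeState:
    """Composition vector plus a rolling history window and a step counter."""

    proportions: np.ndarray
    history: deque = field(default_factory=lambda: deque(maxlen=10))
    time: int = 0

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float).reshape(-1)
        if np.any(self.proportions < 0):
            raise ParameterError("proportions must be non-negative")


def uniform_state(n: int, window: int = 10) -> MicrobiomeState:
    """Initial composition x_i = 1/N (the model's default starting point)."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    state = MicrobiomeState(np.full(n, 1.0 / n), deque(maxlen=window))
    state.history.append(state.proportions.copy())
    return state


@dataclass
class InteractionMatrix:
    """GLV interaction matrix: -1 diagonal, -delta off-diagonals."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(np.diag(self.values), -1.0):
            raise ParameterError("interaction matrix diagonal must be -1")
        off = self.values[~np.eye(self.values.shape[0], dtype=bool)]
        if off.size and np.ptp(off) != 0:
            raise ParameterError("off-diagonal entries must all equal -delta")


def build_interaction_matrix(n: int, delta: float) -> InteractionMatrix:
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if delta < 0:
        raise ParameterError(f"delta must be >= 0, got {delta}")
    a = np.full((n, n), -float(delta))
    np.fill_diagonal(a, -1.0)
    return InteractionMatrix(a)


def _inflow(n: int, params: DynamicsParams) -> float:
    if params.inflow_mode == "per_strain_scaled":
        return params.mu / n
    if params.inflow_mode == "per_strain_constant":
        return params.mu
    return 0.0


def step_normalized(
    state: MicrobiomeState,
    r: np.ndarray,
    strains: StrainSet,
    params: DynamicsParams,
) -> MicrobiomeState:
    """Advance the normalized competition model by one step.

    Applies the per-strain Euler update, clips negative intermediates to
    zero, normalizes, adds inflow, and normalizes again.
    """
    x = state.proportions
    r = np.asarray(r, dtype=float).reshape(-1)
    y = x + x * (r - params.s * x - strains.cost)
    y = np.maximum(y, 0.0)
    tot = y.sum()
    inflow = _inflow(x.size, params)
    if tot <= 0.0:
        if inflow == 0.0:
            raise DegenerateCommunityError(
                f"community collapsed to zero at step {state.time} with no inflow"
            )
        y = np.zeros_like(y)
    else:
        y = y / tot
    if inflow > 0.0:
        y = y + inflow
        y = y / y.sum()
    new = MicrobiomeState(y, state.history, state.time + 1)
    new.history.append(y.copy())
    return new


def step_glv(
    state: MicrobiomeState,
    r: np.ndarray,
    A: InteractionMatrix,
    params: DynamicsParams,
) -> MicrobiomeState:
    """Forward-Euler step (size 1) of the GLV variant; no normalization."""
    x = state.proportions
    r = np.asarray(r, dtype=float).reshape(-1)
    y = x + x * (r + A.values @ x) + _inflow(x.size, params)
    y = np.maximum(y, 0.0)
    if np.any(y > params.divergence_ceiling):
        raise InstabilityError(
            f"abundance exceeded ceiling {params.divergence_ceiling} at step {state.time}"
        )
    new = MicrobiomeState(y, state.history, state.time + 1)
    total = y.sum()
    new.history.append(y / total if total > 0 else y.copy())
    return new
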