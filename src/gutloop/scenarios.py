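"""Full simulation scenarios, metrics, ensembles and parameter sweeps.

Two scenarios are provided.  The *two-strain* scenario follows a host whose
baseline behavior is a Laplace random walk on [0, 1], with an affecting
strain at coordinate 0 competing against a non-affecting strain at 1 — the
setting in which feedback production can pay for its cost.  The *addiction*
scenario follows a three-phase baseline schedule (equilibrium at the origin,
addiction up to severity R for tau steps, withdrawal back toward 0 for a
fixed horizon) through a community of N randomly sampled strains, and
measures how the microbiome's feedback distorts the schedule: the behavior
integrals phi(Addiction) / phi(Withdrawal) and the maximal relapse.
"""

from __future__ import annotations

from dataclasses import dataclass
import itertools

import numpy as np
import pandas as pd

from . import _kernels as K
from .config import SimConfig
from .errors import (
    DegenerateCommunityError,
    InstabilityError,
    ParameterError,
    StateError,
    UndefinedFoldError,
)
from .strains import StrainSet, sample_strains, two_strain_set

__all__ = [
    "TrajectoryRecord",
    "MetricsRow",
    "run_two_strain",
    "run_addiction",
    "detect_stabilization",
    "phi",
    "max_relapse",
    "max_rise",
    "run_ensemble",
    "sweep",
    "derive_cell_seed",
]

_DYN_CODE = {"normalized": K.DYN_NORMALIZED, "glv": K.DYN_GLV}
_FB_CODE = {"reward_circuit": K.FB_REWARD, "direct_pull": K.FB_DIRECT_PULL}
_INFLOW_CODE = {
    "per_strain_scaled": K.INFLOW_SCALED,
    "per_strain_constant": K.INFLOW_CONSTANT,
    "none": K.INFLOW_NONE,
}
PHASE_NAMES = {
    K.PHASE_ADDICTION: "addiction",
    K.PHASE_WITHDRAWAL: "withdrawal",
    K.PHASE_WALK: "walk",
}


@dataclass
class TrajectoryRecord:
    """Realized behavior and (thinned) composition over the scheduled steps.

    ``b1`` covers the post-equilibration timeline only (the equilibrium phase
    holds the behavior at its starting point); phase boundaries are indices
    into ``b1``.  ``addiction_start``/``withdrawal_start`` are -1 for the
    two-strain random walk.
    """

    b1: np.ndarray
    phase: np.ndarray
    addiction_start: int
    withdrawal_start: int
    end: int
    proportions: np.ndarray | None = None
    thin: int = 1
    equilibration_steps: int = 0
    stabilized: bool = True

    def __post_init__(self) -> None:
        if self.addiction_start >= 0 and self.withdrawal_start >= 0:
            if not (self.addiction_start <= self.withdrawal_start <= self.end):
                raise ParameterError("phase boundaries must be ordered and in range")
        if self.end > self.b1.size:
            raise ParameterError("phase boundaries must be ordered and in range")


@dataclass
class MetricsRow:
    """Per-run scalar outcomes of the addiction scenario."""

    phi_addiction: float
    phi_withdrawal: float
    max_relapse: float
    reached_R: bool
    returned: bool
    final_b1: float


# ---------------------------------------------------------------------------
# metrics


def phi(trajectory: TrajectoryRecord, phase: str) -> float:
    """Unit-step Riemann sum (plain sum) of b1 over the named phase window."""
    if phase == "addiction":
        lo, hi = trajectory.addiction_start, trajectory.withdrawal_start
    elif phase == "withdrawal":
        lo, hi = trajectory.withdrawal_start, trajectory.end
    else:
        raise ParameterError(f"phase must be 'addiction' or 'withdrawal', got {phase!r}")
    if lo < 0 or hi < 0:
        raise StateError(f"trajectory has no {phase} boundary")
    return float(np.sum(trajectory.b1[lo:hi]))


def max_rise(series) -> float:
    """Largest increase between any ordered pair of points, floored at 0.

    Linear-time via suffix maxima: for each t1 the best t2 > t1 is the
    running maximum of the tail.
    """
    x = np.asarray(series, dtype=float).reshape(-1)
    if x.size < 2:
        return 0.0
    suffix_max = np.maximum.accumulate(x[::-1])[::-1]
    return float(max(0.0, np.max(suffix_max[1:] - x[:-1])))


def max_relapse(trajectory: TrajectoryRecord) -> float:
    """Maximal relapse magnitude: largest rise in b1 after withdrawal start."""
    if trajectory.withdrawal_start < 0:
        raise StateError("trajectory has no withdrawal boundary")
    return max_rise(trajectory.b1[trajectory.withdrawal_start:trajectory.end])


def detect_stabilization(history, tol: float, window: int) -> bool:
    """True when consecutive-step composition changes stay below ``tol``
    (max over strains) for ``window`` steps in a row anywhere in ``history``."""
    if tol <= 0:
        raise ParameterError("tol must be > 0")
    h = np.asarray(list(history), dtype=float)
    if h.ndim == 1:
        h = h[:, None]
    if h.shape[0] < window + 1:
        return False
    diffs = np.max(np.abs(np.diff(h, axis=0)), axis=1)
    run = 0
    for d in diffs:
        run = run + 1 if d < tol else 0
        if run >= window:
            return True
    return False


# ---------------------------------------------------------------------------
# scenario runners


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _kernel_args(config: SimConfig, strains: StrainSet, active_from: np.ndarray):
    feat0 = np.ascontiguousarray(strains.features[:, 0])
    rest2 = np.sum(strains.features[:, 1:] ** 2, axis=1)
    return dict(
        feat0=feat0,
        rest2=np.ascontiguousarray(rest2),
        d=np.ascontiguousarray(strains.effect_magnitude),
        cost=np.ascontiguousarray(strains.cost),
        bindep=strains.behavior_independent.astype(np.uint8),
        r_indep=float(config.behavior_independent_rate),
        active_from=np.ascontiguousarray(active_from, dtype=np.int64),
        alpha=float(config.alpha),
        beta=float(config.beta),
        floor_rate=float(config.growth_floor),
        s=float(config.s),
        mu=float(config.mu),
        delta=float(config.delta),
        inflow_mode=_INFLOW_CODE[config.inflow_mode],
        dyn_variant=_DYN_CODE[config.dynamics_variant],
        fb_variant=_FB_CODE[config.feedback_variant],
        wm=K.slope_weights(config.omega_m),
        wh=K.slope_weights(config.omega_h),
        slope_tol=float(config.slope_tol),
        thin=int(config.thin),
        ceiling=float(config.divergence_ceiling),
    )


def _raise_kernel_error(err: int, err_step: int) -> None:
    if err == K.ERR_DEGENERATE:
        raise DegenerateCommunityError(
            f"community collapsed to zero at step {err_step} with no inflow"
        )
    if err == K.ERR_DIVERGED:
        raise InstabilityError(f"abundance exceeded the divergence ceiling at step {err_step}")


def run_two_strain(config: SimConfig, rng=None) -> tuple[TrajectoryRecord, float]:
    """Laplace-random-walk competition between an affecting strain at 0 and a
    non-affecting strain at 1; returns the trajectory and the affecting
    strain's final proportion."""
    rng = _as_rng(rng if rng is not None else config.seed)
    _strain_rng, behavior_rng, _new_rng = rng.spawn(3)
    strains = two_strain_set(config.mean_effect, config.cost, config.dims)
    T = config.total_steps_two_strain
    draws = behavior_rng.laplace(0.0, config.sigma, size=T)
    phase_arr = np.full(T, K.PHASE_WALK, dtype=np.int8)
    x0 = np.array([0.5, 0.5])
    args = _kernel_args(config, strains, np.full(2, -1))
    err, err_step, eq_len, _stab, b1, x_thin, x_final, _x_eq = K.simulate_run(
        x0=x0, draws=draws, phase=phase_arr,
        b1_init=0.5, lo=0.0, hi=1.0, r_gate=1.0,
        eq_cap=0, eq_tol=config.stabilization_tol,
        eq_window=config.stabilization_window,
        **args,
    )
    _raise_kernel_error(err, err_step)
    record = TrajectoryRecord(
        b1=b1, phase=phase_arr, addiction_start=-1, withdrawal_start=-1,
        end=T, proportions=x_thin, thin=config.thin,
    )
    return record, float(x_final[0])


def _draw_schedule(behavior_rng: np.random.Generator, config: SimConfig):
    """Signed baseline step draws and phase codes for the addiction scenario."""
    draws_add = behavior_rng.exponential(config.sigma, size=config.tau)
    draws_wd = -behavior_rng.exponential(config.sigma, size=config.withdrawal_horizon)
    draws = np.concatenate([draws_add, draws_wd])
    phase_arr = np.concatenate([
        np.full(config.tau, K.PHASE_ADDICTION, dtype=np.int8),
        np.full(config.withdrawal_horizon, K.PHASE_WITHDRAWAL, dtype=np.int8),
    ])
    return draws, phase_arr


def run_addiction(
    config: SimConfig, rng=None, strains: StrainSet | None = None
) -> tuple[TrajectoryRecord, MetricsRow]:
    """Three-phase addiction scenario through a sampled community.

    Phase 1 equilibrates the microbiome at the origin (capped; a miss is
    recorded on the trajectory, not fatal).  Phase 2 pushes the baseline up
    to R for tau steps, phase 3 pulls it back down for the fixed withdrawal
    horizon; microbial feedback is active in both.  If
    ``intervention_new_strains`` > 0, that many freshly sampled strains join
    the inflow pool at withdrawal start (entering at abundance 0).
    """
    rng = _as_rng(rng if rng is not None else config.seed)
    strain_rng, behavior_rng, newcomer_rng = rng.spawn(3)
    if strains is None:
        strains = sample_strains(
            config.n_strains, config.dims, config.mean_effect,
            config.affecting_fraction, strain_rng, cost=config.cost,
            behavior_independent_fraction=config.behavior_independent_fraction,
        )
    n0 = strains.n_strains
    k = config.intervention_new_strains
    active_from = np.full(n0 + k, -1, dtype=np.int64)
    if k > 0:
        newcomers = sample_strains(
            k, config.dims, config.mean_effect, config.affecting_fraction,
            newcomer_rng, cost=config.cost,
            behavior_independent_fraction=config.behavior_independent_fraction,
        )
        strains = StrainSet(
            features=np.vstack([strains.features, newcomers.features]),
            effect_magnitude=np.concatenate(
                [strains.effect_magnitude, newcomers.effect_magnitude]),
            cost=np.concatenate([strains.cost, newcomers.cost]),
            affecting=np.concatenate([strains.affecting, newcomers.affecting]),
            behavior_independent=np.concatenate(
                [strains.behavior_independent, newcomers.behavior_independent]),
        )
        active_from[n0:] = config.tau  # join at withdrawal start

    draws, phase_arr = _draw_schedule(behavior_rng, config)
    x0 = np.zeros(n0 + k)
    x0[:n0] = 1.0 / n0
    hi = config.R if config.clamp_at_R else 1.0
    args = _kernel_args(config, strains, active_from)
    err, err_step, eq_len, stabilized, b1, x_thin, x_final, _x_eq = K.simulate_run(
        x0=x0, draws=draws, phase=phase_arr,
        b1_init=0.0, lo=0.0, hi=hi, r_gate=config.R,
        eq_cap=config.stabilization_cap, eq_tol=config.stabilization_tol,
        eq_window=config.stabilization_window,
        **args,
    )
    _raise_kernel_error(err, err_step)
    record = TrajectoryRecord(
        b1=b1, phase=phase_arr, addiction_start=0, withdrawal_start=config.tau,
        end=draws.size, proportions=x_thin, thin=config.thin,
        equilibration_steps=int(eq_len), stabilized=bool(stabilized),
    )
    metrics = MetricsRow(
        phi_addiction=phi(record, "addiction"),
        phi_withdrawal=phi(record, "withdrawal"),
        max_relapse=max_relapse(record),
        reached_R=bool(config.tau > 0 and np.max(b1[: config.tau]) >= config.R - 1e-12),
        returned=bool(b1[-1] < config.return_epsilon),
        final_b1=float(b1[-1]),
    )
    return record, metrics


def baseline_phis(config: SimConfig, behavior_rng: np.random.Generator):
    """phi metrics of the no-effect baseline schedule under given draws."""
    draws, phase_arr = _draw_schedule(behavior_rng, config)
    b1 = K.baseline_schedule(draws, phase_arr, 0.0, 0.0,
                             config.R if config.clamp_at_R else 1.0, config.R)
    return float(np.sum(b1[: config.tau])), float(np.sum(b1[config.tau:]))


# ---------------------------------------------------------------------------
# ensembles and sweeps


def _rep_seedseq(base_seed: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(base_seed), int(rep)])


def run_ensemble(
    config: SimConfig, n_reps: int, base_seed: int
) -> tuple[pd.DataFrame, dict]:
    """Seeded replicate runs with feedback, paired against the no-effect
    baseline schedule computed from the very same behavioral draws.

    Returns a per-replicate metrics table and a summary with mean phis,
    fold changes (mean effect phi / mean baseline phi), mean maximal
    relapse, and the fractions of runs not reaching R / not returning.
    """
    if n_reps < 1:
        raise ParameterError(f"n_reps must be >= 1, got {n_reps}")
    rows = []
    for rep in range(n_reps):
        _record, m = run_addiction(
            config, np.random.default_rng(_rep_seedseq(base_seed, rep)))
        # a fresh seed sequence reproduces the same spawn order, so the
        # baseline arm sees the very same behavioral draws
        behavior_rng = np.random.default_rng(
            _rep_seedseq(base_seed, rep)).spawn(3)[1]
        base_add, base_wd = baseline_phis(config, behavior_rng)
        rows.append({
            "rep": rep,
            "phi_addiction": m.phi_addiction,
            "phi_withdrawal": m.phi_withdrawal,
            "baseline_phi_addiction": base_add,
            "baseline_phi_withdrawal": base_wd,
            "max_relapse": m.max_relapse,
            "reached_R": m.reached_R,
            "returned": m.returned,
            "final_b1": m.final_b1,
        })
    df = pd.DataFrame(rows)
    mean_base_add = df["baseline_phi_addiction"].mean()
    mean_base_wd = df["baseline_phi_withdrawal"].mean()
    if mean_base_add == 0 or mean_base_wd == 0:
        raise UndefinedFoldError("baseline mean phi is zero; fold change undefined")
    summary = {
        "n_reps": n_reps,
        "mean_phi_addiction": float(df["phi_addiction"].mean()),
        "mean_phi_withdrawal": float(df["phi_withdrawal"].mean()),
        "mean_baseline_phi_addiction": float(mean_base_add),
        "mean_baseline_phi_withdrawal": float(mean_base_wd),
        "fold_addiction": float(df["phi_addiction"].mean() / mean_base_add),
        "fold_withdrawal": float(df["phi_withdrawal"].mean() / mean_base_wd),
        "mean_max_relapse": float(df["max_relapse"].mean()),
        "frac_not_reached_R": float(1.0 - df["reached_R"].mean()),
        "frac_not_returned": float(1.0 - df["returned"].mean()),
    }
    return df, summary


def derive_cell_seed(base_seed: int, cell_index: int) -> int:
    """Deterministic per-cell seed for sweeps (hash of base seed and cell)."""
    ss = np.random.SeedSequence([int(base_seed), int(cell_index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def sweep(
    grid: dict,
    config: SimConfig,
    n_reps: int,
    base_seed: int,
    couple_effect_to_fraction: bool = False,
) -> pd.DataFrame:
    """Cross-product parameter sweep; one row of ensemble summaries per cell.

    ``grid`` maps SimConfig field names to value lists.  With
    ``couple_effect_to_fraction``, each cell's mean effect is set to
    5 / affecting_fraction so the expected total microbiome effect stays
    constant while the proportion of affecting strains varies.
    """
    import dataclasses as _dc

    valid = {f.name for f in _dc.fields(SimConfig)}
    unknown = sorted(set(grid) - valid)
    if unknown:
        raise ParameterError(f"unknown sweep fields: {', '.join(unknown)}")
    axes = list(grid.items())
    names = [a[0] for a in axes]
    rows = []
    for ci, combo in enumerate(itertools.product(*(a[1] for a in axes))):
        overrides = dict(zip(names, combo))
        if couple_effect_to_fraction:
            frac = overrides.get("affecting_fraction", config.affecting_fraction)
            if frac <= 0:
                raise ParameterError("affecting_fraction must be > 0 to couple mean_effect")
            overrides["mean_effect"] = 5.0 / frac
        cell_config = config.replace(**overrides)
        cell_seed = derive_cell_seed(base_seed, ci)
        _df, summary = run_ensemble(cell_config, n_reps, cell_seed)
        row = {"cell": ci, "cell_seed": cell_seed}
        row.update(overrides)
        row.update(summary)
        rows.append(row)
    return pd.DataFrame(rows)
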