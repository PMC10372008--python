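"""Scenario runners, trajectory metrics, ensembles and sweeps."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gutloop import (
    SimConfig,
    TrajectoryRecord,
    derive_cell_seed,
    detect_stabilization,
    max_relapse,
    max_rise,
    phi,
    run_addiction,
    run_ensemble,
    run_two_strain,
    sweep,
)
from gutloop.errors import ParameterError, StateError


def _record(b1, add=0, wd=None, end=None):
    b1 = np.asarray(b1, float)
    wd = wd if wd is not None else b1.size // 2
    end = end if end is not None else b1.size
    return TrajectoryRecord(b1=b1, phase=np.zeros(b1.size, np.int8),
                            addiction_start=add, withdrawal_start=wd, end=end)


class TestPhi:
    def test_zero_behavior_integrates_to_zero(self):
        assert phi(_record(np.zeros(100)), "addiction") == 0.0

    def test_constant_withdrawal_block(self):
        rec = _record(np.concatenate([np.zeros(10), np.full(100_000, 0.7)]),
                      wd=10)
        assert phi(rec, "withdrawal") == pytest.approx(70_000.0)

    def test_piecewise_series(self):
        rec = _record([0.0, 0.2, 0.4, 0.4], add=0, wd=4, end=4)
        assert phi(rec, "addiction") == pytest.approx(1.0)

    def test_missing_boundary_raises(self):
        rec = _record(np.zeros(10))
        rec.withdrawal_start = -1
        with pytest.raises(StateError):
            phi(rec, "withdrawal")

    def test_unknown_phase_rejected(self):
        with pytest.raises(ParameterError):
            phi(_record(np.zeros(4)), "plateau")


class TestMaxRelapse:
    def test_monotone_decrease_has_no_relapse(self):
        assert max_rise(np.linspace(0.7, 0.0, 50)) == 0.0

    def test_hand_series(self):
        assert max_rise([0.7, 0.6, 0.65, 0.5]) == pytest.approx(0.05)

    def test_constant_series(self):
        assert max_rise(np.full(20, 0.4)) == 0.0

    def test_linear_matches_quadratic_brute_force(self, rng):
        for _ in range(200):
            x = rng.normal(size=rng.integers(2, 60))
            brute = max(0.0, max(x[t2] - x[t1]
                                 for t1 in range(x.size)
                                 for t2 in range(t1 + 1, x.size)))
            assert max_rise(x) == pytest.approx(brute, abs=1e-15)

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=25))
    def test_property_equals_brute_force(self, raw):
        x = np.array(raw)
        brute = max(0.0, max(x[t2] - x[t1]
                             for t1 in range(x.size)
                             for t2 in range(t1 + 1, x.size)))
        assert max_rise(x) == pytest.approx(brute, abs=1e-12)

    def test_uses_withdrawal_window_only(self):
        b1 = np.array([0.0, 0.5, 0.1, 0.1, 0.1])  # rise happens pre-withdrawal
        rec = _record(b1, wd=2)
        assert max_relapse(rec) == 0.0


class TestDetectStabilization:
    def test_constant_composition_stabilizes(self):
        hist = [np.array([0.5, 0.5])] * 20
        assert detect_stabilization(hist, tol=1e-10, window=10)

    def test_single_strain_is_immediately_stable(self):
        hist = [np.array([1.0])] * 6
        assert detect_stabilization(hist, tol=1e-10, window=5)

    def test_oscillation_above_tol_never_stabilizes(self):
        hist = [np.array([0.5 + 0.01 * (-1) ** t, 0.5 - 0.01 * (-1) ** t])
                for t in range(200)]
        assert not detect_stabilization(hist, tol=1e-3, window=10)


class TestRunTwoStrain:
    def test_symmetric_neutral_strains_split_evenly(self):
        # no effect, no cost: mean final proportion within 3 SE of 1/2
        cfg = SimConfig(mean_effect=0.0, cost=0.0, sigma=1e-3, s=0.1,
                        total_steps_two_strain=10_000)
        finals = np.array([
            run_two_strain(cfg, np.random.default_rng(np.random.SeedSequence([3, i])))[1]
            for i in range(200)
        ])
        se = finals.std(ddof=1) / np.sqrt(finals.size)
        assert abs(finals.mean() - 0.5) < 3 * se + 1e-9

    def test_deterministic_under_fixed_seed(self):
        cfg = SimConfig(sigma=1e-3, s=0.1, cost=0.05, mean_effect=5.0,
                        total_steps_two_strain=5_000)
        a = run_two_strain(cfg, np.random.default_rng(11))
        b = run_two_strain(cfg, np.random.default_rng(11))
        assert np.array_equal(a[0].b1, b[0].b1)
        assert a[1] == b[1]

    def test_trajectory_shapes(self):
        cfg = SimConfig(total_steps_two_strain=1_000, thin=10)
        rec, final = run_two_strain(cfg, np.random.default_rng(0))
        assert rec.b1.size == 1_000
        assert rec.proportions.shape == (100, 2)
        assert 0.0 <= final <= 1.0


class TestRunAddiction:
    def test_zero_effect_equals_baseline_schedule(self):
        # with E[d]=0 the realized trajectory is the schedule bit-for-bit
        cfg = SimConfig(n_strains=10, mean_effect=0.0, tau=2_000,
                        withdrawal_horizon=3_000)
        rec, metrics = run_addiction(
            cfg, np.random.default_rng(np.random.SeedSequence([5])))
        behavior_rng = np.random.default_rng(np.random.SeedSequence([5])).spawn(3)[1]
        up = behavior_rng.exponential(cfg.sigma, cfg.tau)
        down = behavior_rng.exponential(cfg.sigma, cfg.withdrawal_horizon)
        b = 0.0
        expected = []
        for step in up:
            b = min(b + step, cfg.R) if b < cfg.R else b
            expected.append(b)
        for step in down:
            b = max(b - step, 0.0)
            expected.append(b)
        assert np.array_equal(rec.b1, np.array(expected))

    def test_metrics_invariants_and_boundaries(self):
        cfg = SimConfig(n_strains=20, tau=3_000, withdrawal_horizon=5_000)
        rec, m = run_addiction(cfg, np.random.default_rng(2))
        assert rec.addiction_start == 0
        assert rec.withdrawal_start == cfg.tau
        assert rec.end == cfg.tau + cfg.withdrawal_horizon
        assert m.phi_addiction >= 0 and m.phi_withdrawal >= 0
        assert 0.0 <= m.max_relapse <= cfg.R
        assert np.all(rec.b1 <= cfg.R + 1e-15)

    def test_equilibration_runs_before_addiction(self):
        cfg = SimConfig(n_strains=5, tau=500, withdrawal_horizon=500)
        rec, _ = run_addiction(cfg, np.random.default_rng(3))
        assert rec.equilibration_steps > 0
        assert rec.stabilized

    def test_intervention_adds_strains_to_inflow_pool(self):
        cfg = SimConfig(n_strains=10, tau=1_000, withdrawal_horizon=2_000,
                        intervention_new_strains=15, thin=1)
        rec, _ = run_addiction(cfg, np.random.default_rng(4))
        x = rec.proportions
        assert x.shape[1] == 25
        # newcomers hold exactly zero before withdrawal, positive after
        assert np.all(x[: cfg.tau, 10:] == 0.0)
        assert np.all(x[-1, 10:] > 0.0)


class TestEnsembleAndSweep:
    def test_zero_effect_fold_is_exactly_one(self):
        cfg = SimConfig(n_strains=5, mean_effect=0.0, tau=1_000,
                        withdrawal_horizon=1_000)
        _df, summary = run_ensemble(cfg, 3, base_seed=9)
        assert summary["fold_addiction"] == pytest.approx(1.0, abs=1e-12)
        assert summary["fold_withdrawal"] == pytest.approx(1.0, abs=1e-12)

    def test_withdrawal_fold_exceeds_one_with_strong_effect(self):
        cfg = SimConfig(n_strains=50, mean_effect=10.0, tau=2_000,
                        withdrawal_horizon=4_000, sigma=1e-3)
        _df, summary = run_ensemble(cfg, 10, base_seed=21)
        assert summary["fold_withdrawal"] > 1.0

    def test_sweep_rows_and_determinism(self):
        cfg = SimConfig(n_strains=5, tau=300, withdrawal_horizon=300)
        grid = {"n_strains": [3, 5], "mean_effect": [0.5, 2.0]}
        a = sweep(grid, cfg, n_reps=2, base_seed=17)
        b = sweep(grid, cfg, n_reps=2, base_seed=17)
        assert len(a) == 4
        assert a.equals(b)

    def test_single_cell_sweep_matches_ensemble(self):
        cfg = SimConfig(n_strains=4, tau=300, withdrawal_horizon=300)
        table = sweep({"mean_effect": [1.0]}, cfg, n_reps=2, base_seed=5)
        _df, summary = run_ensemble(cfg.replace(mean_effect=1.0), 2,
                                    derive_cell_seed(5, 0))
        assert table.loc[0, "fold_withdrawal"] == pytest.approx(
            summary["fold_withdrawal"], abs=1e-15)

    def test_affecting_fraction_coupling_rule(self):
        cfg = SimConfig(n_strains=4, tau=200, withdrawal_horizon=200)
        table = sweep({"affecting_fraction": [0.1, 0.5, 1.0]}, cfg, n_reps=1,
                      base_seed=1, couple_effect_to_fraction=True)
        assert list(table["mean_effect"]) == [50.0, 10.0, 5.0]

    def test_unknown_sweep_field_rejected(self):
        with pytest.raises(ParameterError):
            sweep({"not_a_field": [1]}, SimConfig(), 1, 0)
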