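import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smtf import kinetics, simulate
from smtf.kinetics import (
    DoubleExpFit,
    SurvivalCurve,
    bias_correct_residence_time,
    compile_displacements,
    defocalization_survival,
    fit_double_exponential,
    fit_two_state,
    select_min_duration_threshold,
    survival_probability,
)
from conftest import make_trajectory, trajectories_with_durations


class TestCompileDisplacements:
    def test_jump_cap_per_frameshift(self):
        traj = make_trajectory(0, np.arange(9), np.random.default_rng(0).random((9, 2)))
        ds = compile_displacements([traj], timepoints=8, jumps_per_traj=4)
        assert ds.displacements[1].size == 4
        assert ds.displacements[7].size == 2  # only 2 pairs exist at k=7

    def test_immobile_trajectory_gives_zero_displacements(self):
        traj = make_trajectory(0, np.arange(6), np.zeros((6, 2)))
        ds = compile_displacements([traj])
        for k, r in ds.displacements.items():
            assert np.all(r == 0)

    def test_gap_spanning_displacement_lands_in_longer_group(self):
        # frames 0,1,3,4: the 1->3 jump spans the gap and belongs to k=2
        xy = np.array([[0, 0], [1, 0], [3, 0], [4, 0]], float)
        traj = make_trajectory(0, [0, 1, 3, 4], xy)
        ds = compile_displacements([traj], timepoints=4)
        np.testing.assert_allclose(np.sort(ds.displacements[1]), [1.0, 1.0])
        np.testing.assert_allclose(ds.displacements[2], [2.0])
        np.testing.assert_allclose(ds.displacements[3], [3.0, 3.0])


class TestDefocalizationSurvival:
    def test_immobile_molecule_never_leaves(self):
        assert defocalization_survival(0.0, 0.05, 0.8) == 1.0

    def test_long_time_limit_is_zero(self):
        assert defocalization_survival(3.0, 1e3, 0.8) < 1e-12

    def test_against_brownian_bridge_monte_carlo(self):
        """Eigenfunction series vs a first-passage Monte-Carlo oracle."""
        rng = np.random.default_rng(1)
        D, dt, L = 3.0, 0.03, 0.8
        n, nsub = 400_000, 30
        delta = dt / nsub
        z = rng.uniform(-L / 2, L / 2, n)
        alive = np.ones(n, bool)
        for _ in range(nsub):
            z2 = z + rng.standard_normal(n) * np.sqrt(2 * D * delta)
            inside = np.abs(z2) <= L / 2
            # bridge crossing probabilities for paths inside at both ends
            pu = np.exp(-np.clip((L / 2 - z) * (L / 2 - z2), 0, None) / (D * delta))
            pl = np.exp(-np.clip((z + L / 2) * (z2 + L / 2), 0, None) / (D * delta))
            u = rng.random(n)
            alive &= inside & (u >= pu + pl)
            z = z2
        mc = alive.mean()
        an = defocalization_survival(D, dt, L)
        assert abs(mc - an) < 2e-3

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        d=st.floats(0.1, 10.0),
        dt=st.floats(0.005, 0.2),
        L=st.floats(0.4, 2.0),
    )
    def test_monotone_in_time_and_mobility(self, d, dt, L):
        s = defocalization_survival(d, dt, L)
        assert 0.0 <= s <= 1.0
        assert defocalization_survival(d, 2 * dt, L) <= s + 1e-12
        assert defocalization_survival(2 * d, dt, L) <= s + 1e-12


class TestTwoStateFit:
    def test_single_population_limit(self):
        params = simulate.TwoStateSimParams(
            n_molecules=3000, f_bound=1.0, d_bound=0.05, f_specific=1.0,
            k_off_specific=0.0, k_bleach=2.0, seed=8,
        )
        trajs, _ = simulate.simulate_trajectories(params)
        ds = compile_displacements(trajs)
        fit = fit_two_state(ds, slice_depth=0.8, n_init=5, seed=1)
        assert fit.f_bound >= 0.97

    def test_recovery_at_moderate_n(self):
        params = simulate.preset_params(
            "zld_like", imaging="fast", n_molecules=15000, seed=9
        )
        trajs, _ = simulate.simulate_trajectories(params)
        ds = compile_displacements(trajs)
        fit = fit_two_state(ds, slice_depth=0.8, n_init=5, seed=2)
        assert abs(fit.f_bound - 0.5) < 0.04
        assert fit.d_bound < fit.d_free

    def test_invariant_to_order_and_translation(self):
        params = simulate.preset_params(
            "bcd_like", imaging="fast", n_molecules=2000, seed=10
        )
        trajs, _ = simulate.simulate_trajectories(params)
        ds = compile_displacements(trajs)
        fit_a = fit_two_state(ds, n_init=3, seed=3)
        shuffled = list(reversed(trajs))
        fit_b = fit_two_state(compile_displacements(shuffled), n_init=3, seed=3)
        assert fit_a.f_bound == fit_b.f_bound
        moved = [
            make_trajectory(t.id, t.frames, t.xy + np.array([5.0, -2.0]),
                            dt=t.frame_interval)
            for t in trajs
        ]
        fit_c = fit_two_state(compile_displacements(moved), n_init=3, seed=3)
        assert abs(fit_a.f_bound - fit_c.f_bound) < 5e-3


class TestSurvivalProbability:
    def test_uniform_durations(self):
        sp = survival_probability(trajectories_with_durations([10] * 20))
        assert np.all(sp.survival == 1.0)
        assert sp.durations[0] == pytest.approx(10 * 0.5)

    def test_first_grid_point_is_one_and_non_increasing(self, rng):
        ks = rng.integers(2, 40, size=200)
        sp = survival_probability(trajectories_with_durations(ks))
        assert sp.survival[0] == 1.0
        assert np.all(np.diff(sp.survival) <= 0)

    def test_exponential_durations_match_exp_curve(self, rng):
        dt = 0.01
        t = rng.exponential(1.0, size=4000)
        ks = np.maximum(2, np.ceil(t / dt).astype(int))
        sp = survival_probability(trajectories_with_durations(ks, dt=dt))
        expected = np.exp(-(sp.durations - sp.durations[0]))
        assert np.max(np.abs(sp.survival - expected)) < 0.03


class TestDoubleExponentialFit:
    @staticmethod
    def _curve(f, kns, ks, dt=0.5, kmax=60):
        t = np.arange(1, kmax) * dt
        y = f * np.exp(-kns * t) + (1 - f) * np.exp(-ks * t)
        return SurvivalCurve(t, y / y[0], 1000, dt)

    def test_single_exponential_limit(self):
        sp = self._curve(0.0, 2.0, 0.33)
        fit = fit_double_exponential(sp, 1)
        assert abs(fit.k_s - 0.33) < 0.02

    def test_mixture_recovery_from_sampled_durations(self, rng):
        f, kns, ks, dt = 0.7, 2.0, 0.2, 0.5
        n = 10000
        fast = rng.random(n) < f
        t = np.where(fast, rng.exponential(1 / kns, n), rng.exponential(1 / ks, n))
        frames = np.maximum(2, np.ceil(t / dt).astype(int))
        sp = survival_probability(trajectories_with_durations(frames, dt=dt))
        fit = fit_double_exponential(sp, 1)
        assert abs(fit.k_s - ks) / ks < 0.10

    def test_analytic_mixture_exact(self):
        sp = self._curve(0.6, 3.0, 0.15)
        fit = fit_double_exponential(sp, 1)
        assert abs(fit.k_ns - 3.0) < 0.05
        assert abs(fit.k_s - 0.15) < 0.003

    def test_too_few_points_rejected(self):
        sp = self._curve(0.5, 2.0, 0.2, kmax=5)
        with pytest.raises(ValueError, match="usable"):
            fit_double_exponential(sp, 1)


class TestThresholdSelection:
    def test_clean_data_converges_early(self):
        sp = TestDoubleExponentialFit._curve(0.6, 2.0, 0.2)
        assert select_min_duration_threshold(sp, range(1, 9)) <= 2

    def test_extra_fast_component_delays_convergence(self, rng):
        dt, n = 0.5, 30000
        u = rng.random(n)
        # three-component mixture with a dominant sub-second component
        t = np.where(
            u < 0.55,
            rng.exponential(0.25, n),
            np.where(u < 0.8, rng.exponential(0.8, n), rng.exponential(5.0, n)),
        )
        frames = np.maximum(2, np.ceil(t / dt).astype(int))
        sp3 = survival_probability(trajectories_with_durations(frames, dt=dt))
        u2 = rng.random(n)
        t2 = np.where(u2 < 0.55, rng.exponential(0.8, n), rng.exponential(5.0, n))
        frames2 = np.maximum(2, np.ceil(t2 / dt).astype(int))
        sp2 = survival_probability(trajectories_with_durations(frames2, dt=dt))
        thr3 = select_min_duration_threshold(sp3, range(1, 9))
        thr2 = select_min_duration_threshold(sp2, range(1, 9))
        assert thr3 >= thr2

    def test_non_converging_scan_warns_and_returns_max(self):
        # broad log-spaced rate mixture: the fitted slow rate drifts with
        # every extra duration cut and never settles
        dt = 0.5
        t = np.arange(1, 80) * dt
        rates = np.geomspace(0.05, 5.0, 30)
        y = np.exp(-rates[None, :] * t[:, None]).mean(axis=1)
        sp = SurvivalCurve(t, y / y[0], 30000, dt)
        with pytest.warns(UserWarning, match="never converged"):
            thr = select_min_duration_threshold(sp, range(1, 5), rel_tol=1e-4)
        assert thr == 4


class TestBiasCorrection:
    def test_known_rates(self):
        his = DoubleExpFit(f_fast=0.5, k_ns=2.0, k_s=0.15, min_duration_frames=1)
        est = bias_correct_residence_time(0.33, his)
        assert est.tau_res == pytest.approx(1 / (0.33 - 0.15))
        assert est.tau_res == pytest.approx(5.56, abs=0.01)

    def test_zero_bias(self):
        his = DoubleExpFit(f_fast=0.5, k_ns=2.0, k_s=0.0, min_duration_frames=1)
        assert bias_correct_residence_time(0.4, his).tau_res == pytest.approx(2.5)

    def test_bias_exceeding_signal_rejected(self):
        his = DoubleExpFit(f_fast=0.5, k_ns=2.0, k_s=0.33, min_duration_frames=1)
        with pytest.raises(ValueError, match="bias exceeds signal"):
            bias_correct_residence_time(0.33, his)
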