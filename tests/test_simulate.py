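import numpy as np
import pytest
from scipy import stats

from smtf import simulate
from smtf.simulate import (
    FrapSimParams,
    NucleusSimParams,
    TwoStateSimParams,
    frap_model_curve,
    load_presets,
    preset_params,
    simulate_bound_molecules_in_hubs,
    simulate_frap,
    simulate_his2b_control,
    simulate_nucleus_movie,
    simulate_trajectories,
)


class TestPresets:
    def test_presets_encode_measured_values(self):
        p = load_presets()
        assert p["zld_like"]["f_bound"] == 0.5
        assert p["his2b_like"]["f_bound"] == 0.88
        assert p["zld_like"]["tau_res_s"] == 5.56
        assert p["bcd_like"]["tau_res_s"] == 2.33
        assert np.isinf(p["his2b_like"]["tau_res_s"])

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            preset_params("nope")


class TestTwoStateTrajectories:
    def test_all_motion_sources_off_gives_constant_points(self):
        params = TwoStateSimParams(
            n_molecules=20, f_bound=1.0, d_bound=0.0, sigma_loc=0.0,
            k_off_specific=0.0, k_off_nonspecific=0.0, k_bleach=0.0,
            n_frames=15, seed=1,
        )
        trajs, _ = simulate_trajectories(params)
        assert len(trajs) == 20
        for t in trajs:
            assert len(t) == 15
            assert np.ptp(t.xy, axis=0).max() == 0.0

    def test_bound_fraction_matches_parameter(self):
        params = TwoStateSimParams(n_molecules=10000, f_bound=0.5, seed=2)
        _, truth = simulate_trajectories(params)
        frac = (truth.state != "free").mean()
        assert abs(frac - 0.5) < 4 / np.sqrt(10000)  # binomial error

    def test_mean_specific_bound_duration(self):
        """k_off 0.18/s with all other losses off: mean duration 1/0.18."""
        params = TwoStateSimParams(
            n_molecules=20000, f_bound=1.0, f_specific=1.0,
            k_off_specific=0.18, k_bleach=0.0, slice_depth=np.inf,
            frame_interval=0.5, exposure=0.5, n_frames=10, seed=3,
        )
        _, truth = simulate_trajectories(params)
        mean = truth.t_unbind.mean()
        assert abs(mean - 1 / 0.18) < 4 * (1 / 0.18) / np.sqrt(20000)

    def test_deterministic_given_seed(self):
        params = preset_params("bcd_like", n_molecules=200, seed=11)
        t1, g1 = simulate_trajectories(params)
        t2, g2 = simulate_trajectories(params)
        assert len(t1) == len(t2)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.xy, b.xy)
        assert g1.equals(g2)


class TestHis2bControl:
    def test_specific_class_never_unbinds(self):
        params = preset_params(
            "his2b_like", imaging="residence", n_molecules=500, seed=4
        )
        assert params.k_off_specific == 0.0
        trajs = simulate_his2b_control(params)
        assert len(trajs) > 0

    def test_bleach_limited_durations_are_exponential(self):
        params = TwoStateSimParams(
            n_molecules=2000, f_bound=1.0, f_specific=1.0,
            k_off_specific=0.0, k_bleach=0.15, slice_depth=np.inf,
            frame_interval=0.5, exposure=0.5, n_frames=120, seed=5,
        )
        _, truth = simulate_trajectories(params)
        # track-end times are bleach times: exponential with rate 0.15
        res = stats.kstest(truth.t_end, "expon", args=(0, 1 / 0.15))
        assert res.pvalue > 0.01

    def test_no_losses_means_full_length_tracks(self):
        params = TwoStateSimParams(
            n_molecules=50, f_bound=1.0, f_specific=1.0, k_off_specific=0.0,
            k_bleach=0.0, slice_depth=np.inf, frame_interval=0.5,
            exposure=0.5, n_frames=30, seed=6,
        )
        trajs = simulate_his2b_control(params)
        assert all(len(t) == 30 for t in trajs)

    def test_his2b_immobile_fraction(self):
        params = preset_params("his2b_like", n_molecules=20000, seed=7)
        _, truth = simulate_trajectories(params)
        frac = (truth.state != "free").mean()
        assert abs(frac - 0.88) < 0.01


class TestNucleusMovie:
    def test_flat_nuclei_without_hubs_or_noise(self):
        p = NucleusSimParams(n_hubs=0, noise_sd=0.0, seed=1)
        movie, hub_mask, labels = simulate_nucleus_movie(p)
        assert hub_mask.sum() == 0
        img = movie.frames[0]
        assert np.all(img[labels > 0] == p.background_level)

    def test_disjoint_nuclei_labelled(self):
        p = NucleusSimParams(
            image_shape=(128, 128),
            nucleus_centers=np.array(
                [[20, 20], [20, 64], [20, 108], [80, 40], [80, 90]]
            ),
            nucleus_radii=np.full(5, 14.0),
            seed=2,
        )
        _, _, labels = simulate_nucleus_movie(p)
        assert labels.max() == 5

    def test_hub_mask_matches_percentile_cut(self):
        p = NucleusSimParams(seed=3)
        _, hub_mask, labels = simulate_nucleus_movie(p)
        # per nucleus, the hub mask covers ~15% of pixels by construction
        for l in range(1, labels.max() + 1):
            m = labels == l
            frac = hub_mask[m].mean()
            assert 0.10 < frac < 0.20

    def test_nucleus_outside_image_rejected(self):
        p = NucleusSimParams(
            image_shape=(64, 64),
            nucleus_centers=np.array([[5.0, 32.0]]),
            nucleus_radii=np.array([20.0]),
        )
        with pytest.raises(ValueError, match="outside"):
            simulate_nucleus_movie(p)


class TestBoundMoleculesInHubs:
    @pytest.mark.parametrize("fold", [1.0, 2.0, 4.0])
    def test_density_ratio_by_exhaustive_count(self, fold):
        rng = np.random.default_rng(0)
        labels = np.zeros((64, 64), dtype=int)
        rr, cc = np.mgrid[0:64, 0:64]
        labels[(rr - 32) ** 2 + (cc - 32) ** 2 <= 25 ** 2] = 1
        hub_mask = (labels > 0) & ((rr - 32) ** 2 + (cc - 32) ** 2 <= 10 ** 2)
        n = 40000
        trajs = simulate_bound_molecules_in_hubs(
            hub_mask, labels, fold, n, seed=9
        )
        # exhaustive per-pixel count oracle
        cin = cout = 0
        for t in trajs:
            c, r = np.floor(t.xy[0] / 0.1).astype(int)
            if hub_mask[r, c]:
                cin += 1
            else:
                cout += 1
        a_in, a_out = hub_mask.sum(), ((labels > 0) & ~hub_mask).sum()
        ratio = (cin / a_in) / (cout / a_out)
        assert abs(ratio - fold) < 0.15 * fold


class TestMS2Volumes:
    def test_path_reproducible_from_seed(self):
        p = simulate.LocusSimParams(seed=5, n_timepoints=3)
        a = simulate.simulate_ms2_volumes(p)
        b = simulate.simulate_ms2_volumes(p)
        assert a.path.equals(b.path)
        np.testing.assert_array_equal(a.mcp.frames, b.mcp.frames)

    def test_cytoplasm_brighter_than_nucleoplasm(self):
        p = simulate.LocusSimParams(seed=6, n_timepoints=1, noise_sd=0.0)
        sim = simulate.simulate_ms2_volumes(p)
        inside = sim.mcp.frames[0][:, sim.nucleus_labels > 0]
        outside = sim.mcp.frames[0][:, sim.nucleus_labels == 0]
        assert np.median(outside) > np.median(inside)

    def test_invalid_contrast_rejected(self):
        with pytest.raises(ValueError):
            simulate.LocusSimParams(cytoplasm_level=10, nucleoplasm_level=40)


class TestFrapSim:
    def test_noise_free_curve_equals_model(self):
        p = FrapSimParams(noise_sd=0.0, control_drift=1.0, dark_level=0.0,
                          n_spots=1, seed=1)
        exp = simulate_frap(p)
        np.testing.assert_allclose(
            exp.bleach[0, p.n_pre :], frap_model_curve(p), rtol=1e-12
        )

    def test_zero_amplitudes_give_flat_recovery(self):
        p = FrapSimParams(a_amp=0.0, b_amp=0.0, noise_sd=0.0,
                          control_drift=1.0, dark_level=0.0, n_spots=1)
        exp = simulate_frap(p)
        np.testing.assert_allclose(exp.bleach[0], 1.0)

    def test_slow_component_half_time(self):
        p = FrapSimParams(b_amp=0.4, k_b=np.log(2) / 5.0)
        t = np.log(2) / p.k_b
        assert abs(t - 5.0) < 1e-12

    def test_amplitude_invariant_violation(self):
        with pytest.raises(ValueError):
            FrapSimParams(a_amp=0.7, b_amp=0.5)
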