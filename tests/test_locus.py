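import numpy as np
import pytest
from scipy import stats

from smtf import simulate
from smtf.io import Movie
from smtf.locus import (
    LocusDetection,
    average_and_radial_profile,
    contrast_filter,
    crop_windows,
    detect_loci,
    track_loci,
)


def gaussian_volume(shape=(12, 64, 64), center=(6, 30, 40), amp=500.0,
                    sigma=1.5, base=40.0):
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    sig_z = sigma * 0.1 / 0.25
    return base + amp * np.exp(
        -((yy - center[1]) ** 2 + (xx - center[2]) ** 2) / (2 * sigma ** 2)
        - ((zz - center[0]) ** 2) / (2 * sig_z ** 2)
    )


class TestDetectLoci:
    def test_empty_volume(self):
        assert detect_loci(np.zeros((8, 32, 32))) == []

    def test_single_locus_centroid_within_one_voxel(self):
        v = gaussian_volume() + np.random.default_rng(0).normal(0, 3, (12, 64, 64))
        dets = detect_loci(v)
        assert len(dets) == 1
        d = dets[0]
        assert abs(d.x / 0.1 - 0.5 - 40) < 1.0
        assert abs(d.y / 0.1 - 0.5 - 30) < 1.0
        assert abs(d.z / 0.25 - 0.5 - 6) < 1.0

    def test_size_filter_removes_extremes(self):
        v = np.zeros((8, 64, 64))
        v[4, 10, 10] = 1e5              # hot voxel: small DoG blob (~50 vox)
        v[:, 30:60, 30:60] = 1e4        # huge bright block: large components
        dets = detect_loci(v, size_range=(60, 300))
        assert dets == []
        # without the size filter both structures are detected
        assert len(detect_loci(v, size_range=(1, 10 ** 6))) >= 2


class TestContrastFilter:
    def test_locus_in_dark_nucleoplasm_kept(self):
        v = gaussian_volume()
        det = LocusDetection(0, x=40.5 * 0.1, y=30.5 * 0.1, z=6.5 * 0.25)
        keep, refined = contrast_filter(det, v)
        assert keep
        assert refined.contrast_ratio > 5

    def test_bright_cytoplasm_detection_discarded(self):
        v = np.full((12, 64, 64), 200.0)
        v += gaussian_volume(amp=60.0, base=0.0)  # weak bump on bright bg
        det = LocusDetection(0, x=40.5 * 0.1, y=30.5 * 0.1, z=6.5 * 0.25)
        keep, _ = contrast_filter(det, v, min_ratio=2.0)
        assert not keep

    def test_flat_volume_ratio_one_discarded(self):
        v = np.full((8, 32, 32), 50.0)
        det = LocusDetection(0, x=1.6, y=1.6, z=1.0)
        keep, refined = contrast_filter(det, v)
        assert not keep
        assert refined.contrast_ratio == pytest.approx(1.0)


class TestTrackLoci:
    def test_drifting_locus_single_track(self):
        dets = [
            [LocusDetection(t, x=1.0 + 0.05 * t, y=1.0, z=1.0)]
            for t in range(6)
        ]
        tracks = track_loci(dets, max_disp=0.5)
        assert len(tracks) == 1
        assert len(tracks[0]) == 6

    def test_two_nuclei_no_switches(self):
        dets = [
            [
                LocusDetection(t, x=1.0, y=1.0 + 0.02 * t, z=1.0),
                LocusDetection(t, x=5.0, y=1.0 - 0.02 * t, z=1.0),
            ]
            for t in range(5)
        ]
        tracks = track_loci(dets, max_disp=0.5)
        assert len(tracks) == 2
        for tr in tracks:
            xs = {round(d.x) for d in tr}
            assert len(xs) == 1

    def test_missing_timepoint_splits_track(self):
        dets = [
            [LocusDetection(0, 1.0, 1.0, 1.0)],
            [],
            [LocusDetection(2, 1.0, 1.0, 1.0)],
        ]
        tracks = track_loci(dets, max_disp=0.5)
        assert len(tracks) == 2


def _square_nucleus_setup(n_t=1, img=96, fill=100.0):
    labels = np.zeros((img, img), int)
    rr, cc = np.mgrid[0:img, 0:img]
    labels[(rr - 48) ** 2 + (cc - 48) ** 2 <= 40 ** 2] = 1
    frames = np.full((n_t, 4, img, img), fill, dtype=float)
    movie = Movie(frames=frames, pixel_size_xy=0.1, frame_interval=5.0,
                  voxel_size_z=0.25, channel_label="tf")
    return labels, movie


class TestCropWindows:
    def test_central_locus_keeps_both_windows(self):
        labels, movie = _square_nucleus_setup()
        track = [LocusDetection(0, x=4.8, y=4.8, z=0.5)]
        ts, rs, log = crop_windows(track, movie, labels)
        assert log["kept"] == 1
        assert ts.shape == rs.shape == (1, 23, 23)

    def test_edge_locus_without_control_discarded(self):
        labels, movie = _square_nucleus_setup()
        # near the nucleus edge: own window fits nowhere
        track = [LocusDetection(0, x=1.2, y=4.8, z=0.5)]
        ts, rs, log = crop_windows(track, movie, labels)
        assert log["kept"] == 0

    def test_retained_count_matches_exhaustive_geometric_oracle(self):
        """Window/control retention equals brute-force enumeration."""
        labels, movie = _square_nucleus_setup()
        px = 0.1
        half = int(round(2.18 / 2 / px))
        off = 2.6 / px

        def oracle_keep(r0, c0):
            def box_ok(r, c):
                r1, r2 = r - half, r + half + 1
                c1, c2 = c - half, c + half + 1
                if r1 < 0 or c1 < 0 or r2 > 96 or c2 > 96:
                    return False
                return bool(np.all(labels[r1:r2, c1:c2] == 1))

            if not box_ok(r0, c0):
                return False
            for ang in np.deg2rad(np.arange(0, 360, 10)):
                rc = int(round(r0 + off * np.sin(ang)))
                cc = int(round(c0 + off * np.cos(ang)))
                if 0 <= rc < 96 and 0 <= cc < 96 and box_ok(rc, cc):
                    return True
            return False

        grid = np.arange(8, 90, 7)
        track = []
        expected = 0
        for r in grid:
            for c in grid:
                track.append(
                    LocusDetection(0, x=(c + 0.5) * px, y=(r + 0.5) * px, z=0.5)
                )
                expected += oracle_keep(r, c)
        _, _, log = crop_windows(track, movie, labels)
        assert log["kept"] == expected


class TestRadialProfile:
    def test_uniform_field_profile_is_one(self):
        stack = np.full((10, 23, 23), 7.5)
        _, prof = average_and_radial_profile(stack)
        np.testing.assert_allclose(prof.mean, 1.0, atol=1e-12)

    def test_gaussian_enrichment_matches_closed_form(self):
        # windows containing 1 + a*exp(-r^2 / 2 s^2) plus noise
        a, s_px = 0.5, 3.0
        rng = np.random.default_rng(4)
        rr, cc = np.mgrid[0:23, 0:23]
        r2 = (rr - 11.0) ** 2 + (cc - 11.0) ** 2
        base = 1.0 + a * np.exp(-r2 / (2 * s_px ** 2))
        stack = base[None] + rng.normal(0, 0.05, (500, 23, 23))
        _, prof = average_and_radial_profile(stack, pixel_size=0.1)
        dist = np.sqrt(r2)
        for b in range(prof.mean.size):
            m = np.floor(dist).astype(int) == b
            expected = base[m].mean()
            assert abs(prof.mean[b] - expected) < 0.05 * expected

    def test_control_windows_indistinguishable_without_enrichment(self):
        """TS vs RS: per-annulus t-tests find nothing at alpha=0.01."""
        p = simulate.LocusSimParams(seed=30, tf_enrichment_amplitude=0.0,
                                    n_timepoints=5)
        sim = simulate.simulate_ms2_volumes(p)
        ts_all, rs_all = [], []
        for nuc in (1, 2):
            path = sim.path[sim.path.nucleus == nuc]
            track = [
                LocusDetection(int(row.timepoint), row.x, row.y, row.z)
                for row in path.itertuples()
            ]
            ts, rs, _ = crop_windows(track, sim.tf, sim.nucleus_labels)
            if len(ts):
                ts_all.append(ts)
                rs_all.append(rs)
        ts = np.concatenate(ts_all)
        rs = np.concatenate(rs_all)
        _, prof_ts = average_and_radial_profile(ts)
        _, prof_rs = average_and_radial_profile(rs)
        nbins = prof_ts.mean.size
        alpha = 0.01 / nbins  # Bonferroni
        rr, cc = np.mgrid[0:23, 0:23]
        dist = np.floor(np.hypot(rr - 11, cc - 11)).astype(int)
        for b in range(nbins):
            m = dist == b
            t, pval = stats.ttest_ind(
                ts[:, m].mean(axis=1), rs[:, m].mean(axis=1)
            )
            assert pval > alpha
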