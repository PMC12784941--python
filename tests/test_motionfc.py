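"""Framewise displacement, window selection, motion regression, connectivity."""

import numpy as np
import pytest

from corticothal import motionfc
from corticothal.motionfc import (
    MotionTrace,
    ROITimeSeriesSet,
    ScanQC,
    apply_scan_discard_rule,
    fisher_z,
    framewise_displacement,
    regress_motion,
    roi_connectivity,
    select_least_motion_window,
)
from corticothal.synth import generate_roi_timeseries


def fd_oracle(translations, rotations, radius):
    """Independent element-wise recomputation of framewise displacement."""
    n = len(translations)
    fd = [0.0]
    for t in range(1, n):
        s = sum(abs(translations[t][a] - translations[t - 1][a]) for a in range(3))
        s += radius * sum(abs(rotations[t][a] - rotations[t - 1][a]) for a in range(3))
        fd.append(s)
    return np.array(fd)


def window_oracle(fd, length, exclude_first):
    """Exhaustive search over all admissible windows, earliest tie wins."""
    best_start, best_mean = None, np.inf
    for s in range(exclude_first, len(fd) - length + 1):
        m = fd[s : s + length].mean()
        if m < best_mean:
            best_start, best_mean = s, m
    return best_start, best_mean


class TestFramewiseDisplacement:
    def test_constant_motion_gives_zero_fd(self):
        motion = MotionTrace(np.full((50, 3), 1.3), np.full((50, 3), -0.2))
        fd = framewise_displacement(motion)
        assert np.all(fd.fd == 0) and fd.mean_fd == 0 and fd.max_fd == 0

    def test_single_translation_step(self):
        tr = np.zeros((100, 3))
        tr[40:, 1] = 0.1  # persistent 0.1 mm offset entering at volume 40
        fd = framewise_displacement(MotionTrace(tr, np.zeros((100, 3))))
        assert fd.fd[40] == pytest.approx(0.1)
        assert np.all(np.delete(fd.fd, 40) == 0)

    def test_matches_bruteforce_oracle(self, rng):
        tr = rng.normal(0, 0.01, (200, 3))
        rot = rng.normal(0, 0.002, (200, 3))
        fd = framewise_displacement(MotionTrace(tr, rot), rotation_radius_mm=5.0)
        np.testing.assert_allclose(fd.fd, fd_oracle(tr, rot, 5.0), atol=1e-12)
        assert fd.mean_fd == pytest.approx(fd.fd.mean())
        assert fd.max_fd == pytest.approx(fd.fd.max())
        assert fd.fd[0] == 0 and np.all(fd.fd >= 0)

    def test_nonfinite_parameters_name_the_volume(self):
        tr = np.zeros((10, 3))
        tr[7, 2] = np.nan
        with pytest.raises(ValueError, match="volume 7"):
            framewise_displacement(MotionTrace(tr, np.zeros((10, 3))))


class TestWindowSelection:
    def test_flat_trace_earliest_tiebreak(self):
        sel = select_least_motion_window(np.ones(900), 300, 300)
        assert sel.start == 300 and sel.length == 300

    def test_window_avoids_single_spike(self):
        fd = np.zeros(900)
        fd[450] = 5.0
        sel = select_least_motion_window(fd, 300, 300)
        assert not (sel.start <= 450 < sel.stop)
        assert sel.criterion_value == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            fd = rng.gamma(1.5, 0.02, size=900)
            sel = select_least_motion_window(fd, 300, 300)
            start, mean = window_oracle(fd, 300, 300)
            assert sel.start == start
            assert sel.criterion_value == pytest.approx(mean, abs=1e-12)

    def test_short_scan_reports_required_length(self):
        with pytest.raises(ValueError, match="at least 600"):
            select_least_motion_window(np.zeros(599), 300, 300)


class TestScanDiscardRule:
    @pytest.mark.parametrize(
        "n_removed, expect_discarded", [(21, True), (20, False), (0, False), (30, True)]
    )
    def test_strictly_more_than_threshold(self, n_removed, expect_discarded):
        qc = apply_scan_discard_rule(ScanQC(n_removed=n_removed))
        assert qc.discarded is expect_discarded

    def test_removed_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            ScanQC(n_removed=31, n_components=30)


class TestMotionRegression:
    def test_exact_linear_combination_yields_zero_residuals(self, rng):
        params = rng.normal(size=(300, 6))
        motion = MotionTrace(params[:, :3], params[:, 3:])
        series = params @ rng.normal(size=(6, 4)) + rng.normal(size=4)
        resid = regress_motion(series, motion)
        assert np.sqrt((resid**2).mean()) < 1e-8

    def test_zero_motion_demeans_only(self, rng):
        series = rng.normal(size=(100, 3)) + 5.0
        motion = MotionTrace(np.zeros((100, 3)), np.zeros((100, 3)))
        resid = regress_motion(series, motion)
        np.testing.assert_allclose(resid, series - series.mean(0), atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self, rng):
        params = rng.normal(size=(400, 6))
        motion = MotionTrace(params[:, :3], params[:, 3:])
        series = rng.normal(size=(400, 5))
        window = select_least_motion_window(np.abs(rng.normal(size=700)), 300, 300)
        # regression restricted to the analyzed window
        resid = regress_motion(
            np.vstack([series, rng.normal(size=(300, 5))]),
            MotionTrace(
                np.vstack([params[:, :3], rng.normal(size=(300, 3))]),
                np.vstack([params[:, 3:], rng.normal(size=(300, 3))]),
            ),
            window,
        )
        assert resid.shape == (300, 5)
        x = np.column_stack(
            [
                np.ones(300),
                np.vstack([params[:, :3], rng.normal(size=(300, 3))])[window.slice],
            ]
        )
        # orthogonality to intercept at minimum
        assert np.abs(resid.sum(axis=0)).max() < 1e-6


class TestROIConnectivity:
    def test_identical_series_clip_rule(self, rng):
        a = rng.normal(size=300)
        series = np.column_stack([a, a])
        fc = roi_connectivity(series)
        assert fc.r[0, 1] == pytest.approx(1.0)
        assert fc.z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_anticorrelated_series(self, rng):
        a = rng.normal(size=300)
        fc = roi_connectivity(np.column_stack([a, -a]))
        assert fc.r[0, 1] == pytest.approx(-1.0)
        assert fc.z[0, 1] == pytest.approx(-np.arctanh(1 - 1e-7))

    def test_sample_r_in_fisher_interval(self):
        # population r = 0.6, n = 300: 99% Fisher-z interval is about [0.44, 0.72]
        target = np.array([[1.0, 0.6], [0.6, 1.0]])
        ts = generate_roi_timeseries(target, 300, 0.0, seed=5)
        fc = roi_connectivity(ts.series)
        assert 0.44 < fc.r[0, 1] < 0.72

    def test_zero_variance_roi_set_missing(self, rng):
        series = np.column_stack([rng.normal(size=100), np.ones(100), rng.normal(size=100)])
        fc = roi_connectivity(series)
        assert np.isnan(fc.r[0, 1]) and np.isnan(fc.r[1, 2])
        assert np.isfinite(fc.r[0, 2])

    def test_symmetry_and_permutation_consistency(self, rng):
        series = rng.normal(size=(200, 4))
        fc = roi_connectivity(series, roi_names=("a", "b", "c", "d"))
        np.testing.assert_allclose(fc.r, fc.r.T)
        np.testing.assert_allclose(fc.z, fc.z.T)
        perm = [2, 0, 3, 1]
        fc_p = roi_connectivity(series[:, perm], roi_names=("c", "a", "d", "b"))
        np.testing.assert_allclose(fc_p.r, fc.r[np.ix_(perm, perm)], atol=1e-12)

    def test_invalid_roi_entries_missing(self, rng):
        series = rng.normal(size=(100, 3))
        fc = roi_connectivity(series, valid=np.array([True, False, True]))
        assert np.isnan(fc.r[0, 1]) and np.isnan(fc.r[1, 2]) and np.isnan(fc.r[1, 1])
        assert np.isfinite(fc.r[0, 2])


class TestFisherZ:
    def test_odd_and_monotone(self):
        r = np.linspace(-0.999, 0.999, 201)
        z = fisher_z(r)
        np.testing.assert_allclose(fisher_z(-r), -z, atol=1e-12)
        assert np.all(np.diff(z) > 0)

    def test_extreme_values_finite(self):
        assert np.isfinite(fisher_z(1.0)) and np.isfinite(fisher_z(-1.0))


class TestPipelineChain:
    def test_discarded_scan_produces_no_fc(self, rng):
        series = ROITimeSeriesSet(("a", "b"), rng.normal(size=(700, 2)))
        motion = MotionTrace(rng.normal(0, 0.01, (700, 3)), rng.normal(0, 1e-4, (700, 3)))
        fd, window, qc, fc = motionfc.connectivity_pipeline(
            series, motion, ScanQC(n_removed=25)
        )
        assert qc.discarded and fc is None
        fd, window, qc, fc = motionfc.connectivity_pipeline(
            series, motion, ScanQC(n_removed=5)
        )
        assert not qc.discarded and fc.n_samples == 300
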