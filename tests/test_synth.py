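"""Synthetic cohort generator: determinism, calibration, ground-truth hygiene."""

import numpy as np
import pytest
from scipy import stats

from corticothal.histoquant import derive_class_thresholds
from corticothal.motionfc import framewise_displacement, select_least_motion_window
from corticothal.synth import (
    NucleiParams,
    SynthConfig,
    generate_cohort,
    generate_motion_trace,
    generate_nuclei,
    generate_roi_timeseries,
    uniform_directions,
)

from conftest import small_config


class TestTimeseriesGenerator:
    def test_target_edge_recovered_within_fisher_interval(self):
        target = np.eye(3)
        target[0, 1] = target[1, 0] = 0.8
        ts = generate_roi_timeseries(target, 300, 0.3, seed=0)
        r = np.corrcoef(ts.series, rowvar=False)[0, 1]
        assert 0.6 < r < 0.95

    def test_white_noise_has_no_lag1_autocorrelation(self):
        ts = generate_roi_timeseries(np.eye(2), 2000, 0.0, seed=1)
        for j in range(2):
            x = ts.series[:, j]
            lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
            assert abs(lag1) < 0.15

    def test_ar_coefficient_sets_lag1_autocorrelation(self):
        ts = generate_roi_timeseries(np.eye(2), 5000, 0.6, seed=2)
        x = ts.series[:, 0]
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert lag1 == pytest.approx(0.6, abs=0.06)

    def test_identity_target_bounds_sample_correlations(self):
        ts = generate_roi_timeseries(np.eye(6), 300, 0.3, seed=3)
        r = np.corrcoef(ts.series, rowvar=False)
        off = r[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.3

    def test_identity_target_mean_fc_near_zero_over_replicates(self):
        vals = []
        for seed in range(50):
            ts = generate_roi_timeseries(np.eye(6), 300, 0.3, seed=seed)
            r = np.corrcoef(ts.series, rowvar=False)
            vals.append(r[np.triu_indices(6, 1)])
        assert abs(np.mean(vals)) < 0.05

    def test_non_psd_target_rejected(self):
        bad = np.array([[1.0, 0.95, -0.9], [0.95, 1.0, 0.8], [-0.9, 0.8, 1.0]])
        with pytest.raises(ValueError, match="positive semidefinite"):
            generate_roi_timeseries(bad, 300, 0.3, seed=0)


class TestMotionGenerator:
    def test_no_spikes_no_jitter_gives_zero_fd(self):
        motion, spikes = generate_motion_trace(
            600, 0.0, 0.15, seed=0, jitter_mm=0.0
        )
        fd = framewise_displacement(motion)
        assert np.all(fd.fd == 0) and spikes.size == 0

    def test_spike_count_within_binomial_band(self):
        # n = 1500, rate 0.01: central 99% band of Binomial(1500, 0.01)
        lo = stats.binom.ppf(0.005, 1500, 0.01)
        hi = stats.binom.ppf(0.995, 1500, 0.01)
        counts = [
            generate_motion_trace(1500, 0.01, 0.15, seed=s)[1].size
            for s in range(10)
        ]
        assert all(lo <= c <= hi for c in counts)

    def test_window_avoids_isolated_spike(self):
        motion, _ = generate_motion_trace(
            1500, 0.0, 0.3, seed=4, jitter_mm=0.0, spike_indices=[420]
        )
        fd = framewise_displacement(motion)
        sel = select_least_motion_window(fd)
        assert not (sel.start <= 420 < sel.stop)

    def test_deterministic_given_seed(self):
        a, _ = generate_motion_trace(800, 0.01, 0.15, seed=9)
        b, _ = generate_motion_trace(800, 0.01, 0.15, seed=9)
        np.testing.assert_array_equal(a.parameters, b.parameters)


class TestNucleiGenerator:
    def test_derived_thresholds_do_not_overlap(self):
        params = NucleiParams(
            neuronal_mean=120.0, neuronal_sd=30.0, glial_mean=20.0, glial_sd=5.0
        )
        table = generate_nuclei(900, 700, params, seed=0)
        th = derive_class_thresholds(
            table[table["true_class"] == "neuronal"]["area_um2"],
            table[table["true_class"] == "glial"]["area_um2"],
        )
        assert th.glial[1] < th.neuronal[0]  # intervals separated

    def test_only_glial_when_no_neuronal(self):
        table = generate_nuclei(0, 25, NucleiParams(), seed=1)
        assert set(table["true_class"]) == {"glial"} and len(table) == 25

    def test_fixed_seed_reproducible(self):
        a = generate_nuclei(50, 50, NucleiParams(), seed=5)
        b = generate_nuclei(50, 50, NucleiParams(), seed=5)
        assert a.equals(b)

    def test_areas_positive(self):
        table = generate_nuclei(500, 500, NucleiParams(glial_mean=2.0, glial_sd=3.0), seed=2)
        assert (table["area_um2"] > 0).all()


class TestCohort:
    def test_study_scale_counts(self):
        cfg = SynthConfig(seed=0, n_tbi=36, n_sham=11)
        # counts only: no need to synthesize imaging for all subjects here
        assert cfg.n_tbi + cfg.n_sham == 47

    def test_small_cohort_membership(self, small_cohort):
        assert small_cohort.n_subjects == 10
        assert len(small_cohort.by_group("TBI")) == 6
        assert len(small_cohort.by_group("SHAM")) == 4
        for s in small_cohort.subjects:
            assert set(s.scans) == {"BL", "W2", "M2", "M6"}
            assert set(s.dwi) == {"M2", "M6"}

    def test_determinism_bit_identical(self):
        cfg = small_config(seed=21, n_tbi=2, n_sham=1)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(
                sa.scans["W2"].timeseries.series, sb.scans["W2"].timeseries.series
            )
            np.testing.assert_array_equal(
                sa.scans["M2"].motion.parameters, sb.scans["M2"].motion.parameters
            )
            np.testing.assert_array_equal(sa.dwi["M6"].signals, sb.dwi["M6"].signals)
            assert sa.truth.latent == sb.truth.latent
            if sa.histology is not None:
                assert sa.histology.nuclei.equals(sb.histology.nuclei)

    def test_different_seeds_differ(self):
        a = generate_cohort(small_config(seed=1, n_tbi=1, n_sham=1))
        b = generate_cohort(small_config(seed=2, n_tbi=1, n_sham=1))
        assert not np.array_equal(
            a.subjects[0].scans["BL"].timeseries.series,
            b.subjects[0].scans["BL"].timeseries.series,
        )

    def test_observed_tables_carry_no_ground_truth(self, small_cohort):
        for s in small_cohort.subjects:
            if s.histology is not None:
                for col in s.histology.nuclei.columns:
                    assert "true" not in col and "latent" not in col
                assert s.truth.nuclei_true_class is not None
            # observed scan records expose only measurement fields
            assert not hasattr(s.scans["BL"], "spike_indices")
            assert not hasattr(s.scans["BL"], "latent")

    def test_tbi_latent_severity_exceeds_sham(self, small_cohort):
        tbi = [s.truth.latent for s in small_cohort.by_group("TBI")]
        sham = [s.truth.latent for s in small_cohort.by_group("SHAM")]
        assert min(tbi) > max(sham)

    def test_non_psd_base_override_rejected(self):
        bad = np.eye(6)
        # violates the correlation triangle inequality: not PSD
        bad[0, 1] = bad[1, 0] = 0.95
        bad[1, 2] = bad[2, 1] = 0.95
        bad[0, 2] = bad[2, 0] = -0.95
        cfg = small_config(fc_base_override=tuple(map(tuple, bad)))
        with pytest.raises(ValueError, match="fc_target"):
            cfg.validate()

    def test_too_short_scan_rejected(self):
        with pytest.raises(ValueError, match="600"):
            small_config(n_volumes=500).validate()

    def test_pet_and_histology_subsets(self, small_cohort):
        scanned = [s for s in small_cohort.subjects if s.pet is not None]
        faulty = [s for s in scanned if s.truth.pet_faulty]
        histo = [s for s in small_cohort.subjects if s.histology is not None]
        assert len(scanned) == 10 and len(faulty) == 1 and len(histo) == 7
        for s in histo:  # histology only on PET-successful animals
            assert s.truth.pet_scanned and not s.truth.pet_faulty


class TestDirections:
    def test_uniform_directions_unit_norm_and_well_conditioned(self):
        d = uniform_directions(42)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)
        # the resulting single-shell design supports a stable tensor fit
        from corticothal.dtimetrics import design_matrix
        from corticothal.synth import default_protocol

        x = design_matrix(default_protocol())
        assert np.linalg.cond(x) < 1e5


class TestFCEdgeCalibration:
    def test_mean_edge_z_within_three_standard_errors(self):
        """Over 50 replicate scans, each edge's mean sample z stays within
        3 standard errors of the population value."""
        target = SynthConfig().base_fc_matrix()
        n, reps = 300, 50
        zs = []
        for seed in range(reps):
            ts = generate_roi_timeseries(target, n, 0.0, seed=seed)
            r = np.clip(np.corrcoef(ts.series, rowvar=False), -0.999999, 0.999999)
            zs.append(np.arctanh(r))
        mean_z = np.mean(zs, axis=0)
        tol = 3.0 / np.sqrt(n - 3) / np.sqrt(reps)
        expected = np.arctanh(np.clip(target, -0.999999, 0.999999))
        iu = np.triu_indices(6, 1)
        assert np.abs(mean_z[iu] - expected[iu]).max() < tol
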