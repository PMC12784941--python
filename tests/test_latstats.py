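"""Delta metrics, t-tests, BH-FDR, Spearman, and the correlation grid."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from corticothal.latstats import (
    bh_fdr,
    build_delta_correlation_matrix,
    delta_metric,
    paired_ttest,
    spearman,
    two_sample_ttest,
)


def bh_oracle(p):
    """q_i = min over ranks j >= rank(i) of m * p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


def rank_pearson_oracle(x, y):
    """Spearman rho as Pearson correlation of mid-ranks."""
    return float(np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1])


class TestDeltaMetric:
    def test_cases(self):
        assert delta_metric(3.0, 3.0) == 0.0
        assert delta_metric(5.0, 2.0) == 3.0
        assert np.isnan(delta_metric(np.nan, 2.0))

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6))
    def test_antisymmetry_under_hemisphere_swap(self, a, b):
        assert delta_metric(a, b) == -delta_metric(b, a)


class TestTwoSampleTTest:
    def test_equal_groups_give_t_zero_p_one(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_pooled_variance_formula(self):
        # means 2 and 5, each sample variance 1, pooled SE = sqrt(2/3)
        res = two_sample_ttest([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
        assert res.df == 4

    def test_welch_option(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [4.0, 6.0, 11.0], equal_variance=False)
        assert res.df != 4  # Welch-Satterthwaite df differs from pooled

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            two_sample_ttest([1.0, 1.0], [2.0, 2.0])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(2024)
        reps, hits = 2000, 0
        for _ in range(reps):
            res = two_sample_ttest(rng.normal(size=10), rng.normal(size=10))
            hits += res.p < 0.05
        assert 0.035 < hits / reps < 0.065

    def test_power_increases_with_effect_size(self):
        rng = np.random.default_rng(7)
        powers = []
        for effect in (0.0, 0.8, 1.6):
            hits = 0
            for _ in range(400):
                res = two_sample_ttest(
                    rng.normal(size=12), rng.normal(effect, 1.0, size=12)
                )
                hits += res.p < 0.05
            powers.append(hits / 400)
        assert powers[0] < powers[1] < powers[2]


class TestPairedTTest:
    def test_identical_pairs(self):
        res = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_constant_nonzero_difference_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_matches_difference_oracle(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        res = paired_ttest(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == 14

    def test_incomplete_pairs_dropped(self, rng):
        a = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        b = np.array([0.5, 2.5, 3.0, 3.0, np.nan])
        res = paired_ttest(a, b)
        assert res.n == 3


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.032])[0] == pytest.approx(0.032)

    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_matches_stepup_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_exhaustive_small_grid(self):
        grid = [0.001, 0.01, 0.04, 0.2, 0.8, 1.0]
        for length in (1, 2, 3):
            for combo in itertools.product(grid, repeat=length):
                np.testing.assert_allclose(
                    bh_fdr(list(combo)), bh_oracle(list(combo)), atol=1e-12
                )

    def test_q_at_least_p_and_order_preserving(self, rng):
        p = rng.uniform(size=20)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)
        # ranking by q never reverses ranking by p
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestSpearman:
    def test_monotone_and_reversed(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        res = spearman(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)
        res_rev = spearman(x, -np.exp(x))
        assert res_rev.rho == pytest.approx(-1.0)

    def test_tied_data_matches_rank_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 4.0])
        res = spearman(x, y)
        assert res.rho == pytest.approx(rank_pearson_oracle(x, y), abs=1e-12)

    def test_pairwise_complete_counting(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([1.0, np.nan, 3.0, 4.0, 5.0, 7.0])
        res = spearman(x, y)
        assert res.n == 4  # only complete pairs enter

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            spearman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="at least 4"):
            spearman(x, y)  # 3 complete pairs

    def test_constant_input_flagged_missing(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(res.rho) and np.isnan(res.p)

    def test_exact_permutation_p_close_to_t_approximation(self, rng):
        x = rng.normal(size=7)
        y = x + rng.normal(0, 0.8, size=7)
        approx = spearman(x, y)
        exact = spearman(x, y, exact=True)
        assert exact.rho == pytest.approx(approx.rho)
        assert abs(exact.p - approx.p) < 0.12

    def test_regression_line_attached(self, rng):
        x = rng.normal(size=20)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.01, size=20)
        res = spearman(x, y)
        assert res.slope == pytest.approx(2.0, abs=0.05)
        assert res.intercept == pytest.approx(1.0, abs=0.05)


def _delta_frame(animals, nucleus, metric, timepoint, values):
    return pd.DataFrame(
        {
            "animal": animals,
            "nucleus": nucleus,
            "metric": metric,
            "timepoint": timepoint,
            "delta": values,
        }
    )


class TestDeltaCorrelationMatrix:
    def test_monotone_limit_detected(self, rng):
        animals = [f"a{i}" for i in range(12)]
        du = rng.normal(size=12)
        deltas = pd.concat(
            [
                _delta_frame(animals, "LN", "U_FEPPA", "W2", du),
                _delta_frame(animals, "LN", "MD", "M2", 2.0 * du + rng.normal(0, 1e-9, 12)),
                _delta_frame(animals, "LN", "FA", "M2", rng.normal(size=12)),
            ]
        )
        out = build_delta_correlation_matrix(deltas, nuclei=("LN",))
        md = out[out["metric"] == "MD"].iloc[0]
        assert md["rho"] == pytest.approx(1.0)
        assert md["significant"]

    def test_small_cells_left_missing(self, rng):
        animals = [f"a{i}" for i in range(8)]
        deltas = pd.concat(
            [
                _delta_frame(animals, "LN", "U_FEPPA", "W2", rng.normal(size=8)),
                _delta_frame(
                    animals, "LN", "MD", "M2",
                    [np.nan] * 6 + list(rng.normal(size=2)),
                ),
            ]
        )
        out = build_delta_correlation_matrix(deltas, nuclei=("LN",))
        row = out.iloc[0]
        assert np.isnan(row["rho"]) and not row["significant"] and row["n"] == 2

    def test_hemisphere_relabeling_flips_rho_sign_only(self, rng):
        animals = [f"a{i}" for i in range(10)]
        du = rng.normal(size=10)
        dm = 1.5 * du + rng.normal(0, 0.3, size=10)
        base = pd.concat(
            [
                _delta_frame(animals, "LN", "U_FEPPA", "W2", du),
                _delta_frame(animals, "LN", "MD", "M2", dm),
            ]
        )
        flipped = base.copy()
        # swapping hemisphere labels negates every delta
        flipped["delta"] = -flipped["delta"]
        rho_base = build_delta_correlation_matrix(base, nuclei=("LN",))["rho"].iloc[0]
        rho_flip = build_delta_correlation_matrix(flipped, nuclei=("LN",))["rho"].iloc[0]
        assert rho_flip == pytest.approx(rho_base)  # both deltas negate: rho unchanged
        half = base.copy()
        half.loc[half["metric"] == "MD", "delta"] *= -1
        rho_half = build_delta_correlation_matrix(half, nuclei=("LN",))["rho"].iloc[0]
        assert rho_half == pytest.approx(-rho_base)
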