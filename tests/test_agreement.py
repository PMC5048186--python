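"""Agreement, calibration, ranking and weighted-kappa statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dietval.agreement import (bland_altman, calibration_slope, correlate,
                               cross_classify, paired_compare, quantile_bins,
                               weighted_kappa)


class TestBlandAltman:
    def test_identical_inputs_collapse(self):
        x = np.array([8.0, 9.0, 10.0, 11.0])
        res = bland_altman(x, x)
        assert res.mean_difference == 0.0
        assert res.sd_difference == 0.0
        assert (res.loa_lower, res.loa_upper) == (0.0, 0.0)

    def test_constant_offset(self):
        x = np.array([8.0, 9.0, 10.0, 11.0])
        res = bland_altman(x, x + 2.0)
        assert res.mean_difference == pytest.approx(-2.0)
        assert res.sd_difference == 0.0
        assert res.trend_slope == 0.0

    def test_five_pair_toy_against_manual_arithmetic(self):
        x = np.array([10.0, 12.0, 9.0, 11.0, 14.0])
        y = np.array([9.0, 13.0, 8.0, 12.0, 10.0])
        res = bland_altman(x, y)
        diff = x - y
        mean_pair = (x + y) / 2.0
        md = diff.sum() / 5.0
        sd = math.sqrt(((diff - md) ** 2).sum() / 4.0)
        assert res.mean_difference == pytest.approx(md, abs=1e-12)
        assert res.sd_difference == pytest.approx(sd, abs=1e-12)
        assert res.loa_lower == pytest.approx(md - 1.96 * sd, abs=1e-12)
        assert res.loa_upper == pytest.approx(md + 1.96 * sd, abs=1e-12)
        # trend: explicit normal equations + t test of the slope
        xc = mean_pair - mean_pair.mean()
        b = float(xc @ diff) / float(xc @ xc)
        a = diff.mean() - b * mean_pair.mean()
        sse = float(((diff - a - b * mean_pair) ** 2).sum())
        se = math.sqrt(sse / 3.0 / float(xc @ xc))
        t_stat = b / se
        p = 2 * stats.t.sf(abs(t_stat), 3)
        assert res.trend_slope == pytest.approx(b, abs=1e-12)
        assert res.trend_p == pytest.approx(p, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_normal_differences_coverage(self):
        rng = np.random.default_rng(6)
        x = rng.normal(10.0, 1.0, 10_000)
        y = x - rng.normal(2.0, 1.5, 10_000)
        res = bland_altman(x, y)
        inside = 100.0 - res.pct_outside_loa
        assert 93.0 <= inside <= 97.0


class TestCalibrationSlope:
    def test_identity_regression(self):
        x = np.array([7.0, 8.5, 9.0, 10.0, 12.0])
        res = calibration_slope(x, x)
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.ci_lower <= 1.0 <= res.ci_upper

    def test_null_slope_construction(self, rng):
        ei = rng.uniform(6, 12, 200)
        tee = np.full(200, 10.0) + rng.normal(0, 0.5, 200)
        res = calibration_slope(ei, tee)
        assert res.ci_lower <= 0.0 + 0.2 and res.slope == pytest.approx(
            0.0, abs=0.2)

    def test_six_pair_toy_against_explicit_formulas(self):
        ei = np.array([6.0, 7.0, 8.0, 9.0, 10.0, 11.0])
        tee = np.array([8.1, 9.3, 9.0, 10.8, 10.9, 12.4])
        res = calibration_slope(ei, tee)
        xc = ei - ei.mean()
        b = float(xc @ tee) / float(xc @ xc)
        a = tee.mean() - b * ei.mean()
        sse = float(((tee - a - b * ei) ** 2).sum())
        se = math.sqrt(sse / 4.0 / float(xc @ xc))
        half = stats.t.ppf(0.975, 4) * se
        assert res.slope == pytest.approx(b, abs=1e-10)
        assert res.ci_lower == pytest.approx(b - half, abs=1e-10)
        assert res.ci_upper == pytest.approx(b + half, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            calibration_slope([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


class TestPairedCompare:
    def test_all_zero_differences_degenerate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = paired_compare(x, x)
        assert res.degenerate
        assert res.n_nonzero == 0

    def test_exact_p_matches_brute_force_enumeration(self):
        x = np.array([10.5, 8.2, 9.7, 12.1, 9.8, 10.9, 11.8, 8.9])
        y = np.array([9.0, 10.5, 9.0, 9.0, 10.0, 9.0, 9.0, 10.0])
        res = paired_compare(x, y)
        d = x - y
        ranks = stats.rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        total = len(d) * (len(d) + 1) / 2
        ws = np.array([
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=len(d))])
        p = min(1.0, 2 * min((ws <= w_plus).mean(), (ws >= w_plus).mean()))
        assert res.p_value == pytest.approx(p, abs=1e-12)
        assert res.statistic == pytest.approx(min(w_plus, total - w_plus))

    def test_zero_differences_dropped_and_counted(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = x + np.array([0.0, 0.0, 0.3, -0.4, 0.5, -0.6, 0.7])
        res = paired_compare(x, y)
        assert res.n_zero == 2
        assert res.n_nonzero == 5

    def test_type_one_error_near_nominal_under_null(self):
        """Symmetric null differences: ~5% of p-values below 0.05."""
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            d = rng.normal(0.0, 1.0, 40)
            res = paired_compare(d, np.zeros(40))
            rejections += res.p_value < 0.05
        rate = rejections / n_rep
        assert 0.03 <= rate <= 0.07


class TestCorrelate:
    def test_perfect_monotone_identity(self, rng):
        x = rng.uniform(0, 10, 25)
        for mode in ("crude_spearman", "adjusted_pearson"):
            assert correlate(x, x, mode).coefficient == pytest.approx(1.0)

    def test_perfect_inversion(self, rng):
        x = rng.uniform(0, 10, 25)
        assert correlate(x, -x, "crude_spearman").coefficient == pytest.approx(-1.0)
        assert correlate(x, -x, "adjusted_pearson").coefficient == pytest.approx(-1.0)

    def test_spearman_with_ties_equals_pearson_on_midranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0, 6.0, 7.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 5.0, 8.0, 7.0])
        got = correlate(x, y, "crude_spearman").coefficient
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        expected = float(np.corrcoef(rx, ry)[0, 1])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestQuantileBins:
    def test_exact_thirds(self):
        bins = quantile_bins(np.arange(1.0, 10.0), 3)
        np.testing.assert_array_equal(bins, [1, 1, 1, 2, 2, 2, 3, 3, 3])

    def test_constant_values_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            bins = quantile_bins(np.full(9, 2.0), 3)
        assert set(bins) == {1}

    def test_boundary_ties_go_to_lower_bin(self):
        values = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        bins = quantile_bins(values, 4)
        boundaries = np.quantile(values, [0.25, 0.5, 0.75])
        for v, b in zip(values, bins):
            expected = 1 + int(np.sum(boundaries < v))
            assert b == expected

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            quantile_bins([1.0, 2.0, 3.0], 1)


class TestCrossClassify:
    def test_identical_bins_full_agreement(self):
        bins = np.array([1, 1, 2, 2, 3, 3])
        res = cross_classify(bins, bins)
        assert res.pct_same == 100.0
        assert res.kappa_weighted == pytest.approx(1.0)

    def test_reversed_balanced_tertiles(self):
        a = np.repeat([1, 2, 3], 10)
        b = np.repeat([3, 2, 1], 10)
        res = cross_classify(a, b)
        # corners (1,3) and (3,1) hold 20 of 30 subjects
        assert res.pct_opposite == pytest.approx(200.0 / 3.0)
        assert res.pct_same == pytest.approx(100.0 / 3.0)

    def test_percentages_partition_to_exactly_hundred(self, rng):
        a = rng.integers(1, 5, 37)
        b = rng.integers(1, 5, 37)
        res = cross_classify(np.maximum(a, 1), np.maximum(b, 1))
        k = res.n_bins
        t = res.table
        intermediate = sum(
            t[i, j] for i in range(k) for j in range(k)
            if abs(i - j) >= 2 and not (
                (i == 0 and j == k - 1) or (i == k - 1 and j == 0)))
        total_pct = (res.pct_same + res.pct_adjacent + res.pct_opposite
                     + 100.0 * intermediate / t.sum())
        assert total_pct == pytest.approx(100.0, abs=1e-9)

    def test_independent_bins_give_near_zero_kappa(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 4, 100_000)
        b = rng.integers(1, 4, 100_000)
        res = cross_classify(a, b)
        assert abs(res.kappa_weighted) < 0.01


def _naive_weighted_kappa(table, scheme):
    """Independent direct-summation implementation (plain double loop)."""
    table = np.asarray(table, dtype=float)
    k = table.shape[0]
    n = table.sum()
    obs = num = 0.0
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    for i in range(k):
        for j in range(k):
            w = abs(i - j) / (k - 1)
            if scheme == "quadratic":
                w = w * w
            obs += w * table[i, j] / n
            num += w * row[i] * col[j]
    return 1.0 - obs / num


class TestWeightedKappa:
    @pytest.mark.parametrize("scheme", ["linear", "quadratic"])
    def test_diagonal_table_is_one(self, scheme):
        assert weighted_kappa(np.diag([5, 7, 3]), scheme) == pytest.approx(1.0)

    def test_balanced_antidiagonal_two_by_two_is_minus_one(self):
        assert weighted_kappa([[0, 8], [8, 0]], "linear") == pytest.approx(-1.0)

    @pytest.mark.parametrize("k", [3, 4])
    @pytest.mark.parametrize("scheme", ["linear", "quadratic"])
    def test_matches_naive_double_loop_on_random_tables(self, k, scheme):
        rng = np.random.default_rng(100 + k)
        for _ in range(200):
            table = rng.integers(0, 30, (k, k)).astype(float)
            if table.sum() == 0:
                table[0, 0] = 1
            assert weighted_kappa(table, scheme) == pytest.approx(
                _naive_weighted_kappa(table, scheme), abs=1e-12)

    def test_matches_sklearn_on_label_expansion(self):
        """Cross-check against an independent library implementation."""
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(8)
        for scheme, weights in (("linear", "linear"),
                                ("quadratic", "quadratic")):
            table = rng.integers(1, 15, (4, 4))
            a, b = [], []
            for i in range(4):
                for j in range(4):
                    a.extend([i] * table[i, j])
                    b.extend([j] * table[i, j])
            expected = sklearn_metrics.cohen_kappa_score(a, b, weights=weights)
            assert weighted_kappa(table, scheme) == pytest.approx(
                expected, abs=1e-12)

    @given(factor=st.integers(2, 50))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_invariant_under_count_scaling(self, factor):
        table = np.array([[10, 3, 1], [4, 12, 5], [0, 6, 9]], dtype=float)
        assert weighted_kappa(table * factor) == pytest.approx(
            weighted_kappa(table), abs=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            weighted_kappa(np.zeros((3, 3)))
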