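"""Data allocation, metrics, residual diagnostics and the test battery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from emgforce import (
    DataError,
    allocate_data,
    bias_t_test,
    bland_altman,
    compare_auc,
    compare_models_rm,
    compute_metrics,
    mann_whitney,
    regression_sample_size,
    roc_youden,
    timing_harness,
)
from emgforce.evaluation import normality_test


class TestAllocateData:
    def test_paper_style_30_20_50_blocks(self):
        s = allocate_data(1000, (0.3, 0.2, 0.5))
        assert s.estimation_idx.size == 300
        assert s.validation_idx.size == 200
        assert s.test_idx.size == 500
        assert s.estimation_idx[0] == 0 and s.test_idx[-1] == 999

    def test_even_5050(self):
        s = allocate_data(10, (0.5, 0.5))
        assert np.array_equal(s.estimation_idx, np.arange(5))
        assert np.array_equal(s.test_idx, np.arange(5, 10))
        assert s.validation_idx.size == 0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.integers(3, 5000),
        st.sampled_from([(0.3, 0.2, 0.5), (0.5, 0.5), (0.7, 0.3), (0.6, 0.2, 0.2)]),
        st.sampled_from(["contiguous", "interleaved"]),
    )
    def test_partition_property(self, n, fractions, scheme):
        s = allocate_data(n, fractions, scheme=scheme)
        parts = [s.estimation_idx, s.validation_idx, s.test_idx]
        union = np.concatenate(parts)
        assert union.size == n
        assert np.array_equal(np.sort(union), np.arange(n))
        sizes = [p.size for p in parts if p.size or len(fractions) == 3]
        for frac, part in zip(fractions, [p for p in parts if not (len(fractions) == 2 and p is s.validation_idx)]):
            assert abs(part.size - n * frac) <= 1

    def test_bad_fractions_rejected(self):
        with pytest.raises(DataError):
            allocate_data(100, (0.5, 0.6))
        with pytest.raises(DataError):
            allocate_data(1, (0.5, 0.3, 0.2))


class TestMetrics:
    def test_perfect_prediction(self, rng):
        y = rng.standard_normal(50)
        m = compute_metrics(y, y, k=3)
        assert m.r == pytest.approx(1.0)
        assert m.R2 == pytest.approx(1.0)
        assert m.adjR2 == pytest.approx(1.0)
        assert m.RMSE == 0.0 and m.MAE == 0.0

    def test_mean_predictor_scores_zero(self, rng):
        y = rng.standard_normal(50)
        m = compute_metrics(y, np.full(50, y.mean()), k=1)
        assert m.R2 == pytest.approx(0.0, abs=1e-12)

    def test_adjusted_r2_formula(self, rng):
        # R2=0.9, N=101, k=10 -> 1 - 0.1*100/90
        y = rng.standard_normal(101)
        # construct predictions with SSE = 0.1 * SST exactly
        sst = np.sum((y - y.mean()) ** 2)
        resid = y - y.mean()
        yhat = y - resid * math.sqrt(0.1)
        m = compute_metrics(y, yhat, k=10)
        assert m.R2 == pytest.approx(0.9, abs=1e-12)
        assert m.adjR2 == pytest.approx(1 - 0.1 * 100 / 90, abs=1e-9)
        assert m.adjR2 <= m.R2

    def test_r_squared_equals_r2_for_ls_fit_with_intercept(self, rng):
        x = rng.standard_normal(200)
        y = 2 * x + rng.standard_normal(200)
        slope, icpt = np.polyfit(x, y, 1)
        m = compute_metrics(y, slope * x + icpt, k=2)
        assert m.r**2 == pytest.approx(m.R2, abs=1e-10)

    def test_negative_r2_reported_not_clipped(self, rng):
        y = rng.standard_normal(30)
        m = compute_metrics(y, y + 10, k=1)
        assert m.R2 < 0

    def test_constant_measured_rejected(self):
        with pytest.raises(DataError, match="SST"):
            compute_metrics(np.ones(10), np.arange(10.0), k=1)


class TestBlandAltman:
    def test_constant_offset(self, rng):
        y = rng.standard_normal(40)
        ba = bland_altman(y, y + 2.0)
        assert ba.bias == pytest.approx(2.0)
        assert ba.sd == pytest.approx(0.0, abs=1e-12)
        assert ba.upper == pytest.approx(2.0) and ba.lower == pytest.approx(2.0)

    def test_bias_and_sd_match_scalar_oracle(self, rng):
        y = rng.standard_normal(100)
        yhat = rng.standard_normal(100)
        ba = bland_altman(y, yhat)
        resid = yhat - y
        assert ba.bias == pytest.approx(resid.mean())
        assert ba.sd == pytest.approx(resid.std(ddof=1))
        assert ba.lower <= ba.bias <= ba.upper

    def test_conventional_limits_flag(self, rng):
        y = rng.standard_normal(100)
        yhat = y + rng.standard_normal(100)
        ba = bland_altman(y, yhat, n_sd=1.96)
        assert ba.upper == pytest.approx(ba.bias + 1.96 * ba.sd)

    def test_residual_regression_line(self, rng):
        y = np.linspace(0, 1, 200)
        yhat = y + 0.5 * y + 0.1  # residual = 0.5*y + 0.1
        ba = bland_altman(y, yhat)
        slope, intercept = ba.residual_regression
        assert slope == pytest.approx(0.5, abs=1e-9)
        assert intercept == pytest.approx(0.1, abs=1e-9)


class TestBiasTTest:
    def test_identical_inputs_convention(self):
        y = np.arange(10.0)
        res = bias_t_test(y, y)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_constant_nonzero_residual_rejects(self):
        y = np.zeros(10)
        res = bias_t_test(y, y + 1.0)
        assert res.p_value < 1e-6

    def test_matches_t_distribution_oracle(self, rng):
        y = rng.standard_normal(1000)
        yhat = y + rng.standard_normal(1000) * 0.5
        res = bias_t_test(y, yhat)
        resid = yhat - y
        t_oracle = resid.mean() / (resid.std(ddof=1) / math.sqrt(resid.size))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), resid.size - 1)
        assert res.statistic == pytest.approx(t_oracle, abs=1e-9)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-9)


class TestRmAnova:
    def test_identical_models_give_f_zero(self, rng):
        col = rng.standard_normal(6)
        S = np.tile(col[:, None], (1, 4))
        omnibus, pairwise = compare_models_rm(S)
        assert omnibus.statistic == 0.0 and omnibus.p_value == 1.0
        assert all(t.adj_p_value == 1.0 for t in pairwise)

    def test_offset_models_with_zero_noise(self, rng):
        base = rng.standard_normal(8)
        S = np.column_stack([base, base + 1.0])
        omnibus, pairwise = compare_models_rm(S)
        assert pairwise[0].p_value < 1e-6
        assert omnibus.p_value < 1e-6

    def test_hand_computed_five_by_three_fixture(self):
        S = np.array([[1, 2, 3], [2, 3, 4], [3, 4, 5], [4, 5, 7], [5, 6, 8]], float)
        omnibus, pairwise = compare_models_rm(S)
        # within-subject ANOVA table computed by hand:
        # SS_models = 14.5333, SS_error = 0.8, df = (2, 8)
        assert omnibus.statistic == pytest.approx(72.666667, abs=1e-5)
        assert omnibus.df == (2, 8)
        assert omnibus.p_value == pytest.approx(7.4099e-06, rel=1e-3)
        assert len(pairwise) == 2
        # Bonferroni with m=2 comparisons
        for t in pairwise:
            assert t.adj_p_value == pytest.approx(min(1.0, 2 * t.p_value))

    def test_incomplete_matrix_rejected(self):
        S = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(DataError):
            compare_models_rm(S)


class TestMannWhitney:
    def test_fully_separated_groups(self):
        res = mann_whitney([1, 2, 3], [10, 11, 12])
        assert res.statistic in (0.0, 9.0)

    def test_identical_groups_p_one_under_enumeration(self):
        res = mann_whitney([5.0, 5.0, 5.0], [5.0, 5.0])
        assert res.p_value == pytest.approx(1.0)

    def test_u_matches_brute_force_pair_counting(self, rng):
        a = rng.integers(0, 5, 8).astype(float)
        b = rng.integers(0, 5, 7).astype(float)
        res = mann_whitney(a, b)
        u_brute = sum(1.0 for x in a for y in b if x > y) + 0.5 * sum(
            1.0 for x in a for y in b if x == y
        )
        assert res.statistic == pytest.approx(u_brute)

    def test_exact_p_matches_permutation_enumeration(self):
        from itertools import combinations

        a = np.array([1.0, 3.0, 5.0])
        b = np.array([2.0, 2.0, 4.0])
        res = mann_whitney(a, b)
        pooled = np.concatenate([a, b])
        mu = a.size * b.size / 2

        def ustat(x, y):
            return sum(1.0 for i in x for j in y if i > j) + 0.5 * sum(
                1.0 for i in x for j in y if i == j
            )

        obs = abs(ustat(a, b) - mu)
        count = total = 0
        for comb in combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(comb)] = True
            total += 1
            if abs(ustat(pooled[mask], pooled[~mask]) - mu) >= obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / total)

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            mann_whitney([], [1.0])


class TestROC:
    def test_perfect_separation(self):
        res = roc_youden([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.youden_j == pytest.approx(1.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_random_scores_near_half_auc(self, rng):
        scores = rng.standard_normal(2000)
        labels = rng.permutation(np.repeat([0, 1], 1000))
        res = roc_youden(scores, labels)
        assert 0.45 < res.auc < 0.55

    def test_auc_equals_ordered_pair_fraction(self):
        scores = np.array([0.2, 0.4, 0.4, 0.6, 0.7, 0.1])
        labels = np.array([0, 1, 0, 1, 1, 0])
        res = roc_youden(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        frac = np.mean([(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg])
        assert res.auc == pytest.approx(frac)

    def test_auc_equals_u_over_n1n0(self, rng):
        scores = rng.standard_normal(60)
        labels = rng.integers(0, 2, 60)
        while np.unique(labels).size < 2:
            labels = rng.integers(0, 2, 60)
        res = roc_youden(scores, labels)
        u = mann_whitney(scores[labels == 1], scores[labels == 0]).statistic
        n1, n0 = (labels == 1).sum(), (labels == 0).sum()
        assert res.auc == pytest.approx(u / (n1 * n0))

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_youden([1.0, 2.0], [1, 1])

    def test_youden_tie_broken_toward_specificity(self):
        # two cutoffs reach J = 0.5; the higher-specificity one must win
        scores = np.array([1, 2, 3, 4, 5, 6, 7, 8], float)
        labels = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        res = roc_youden(scores, labels)
        j = res.tpr - res.fpr
        ties = np.flatnonzero(j >= j.max() - 1e-12)
        assert res.specificity == pytest.approx(1 - res.fpr[ties].min())


class TestCompareAUC:
    def test_feature_against_itself(self, rng):
        scores = rng.standard_normal(40)
        labels = rng.permutation(np.repeat([0, 1], 20))
        r = roc_youden(scores, labels)
        res = compare_auc(r, r)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_separating_beats_random_feature(self, rng):
        labels = np.repeat([0, 1], 100)
        good = labels + 0.1 * rng.standard_normal(200)
        noise = rng.standard_normal(200)
        res = compare_auc(roc_youden(good, labels), roc_youden(noise, labels))
        assert res.p_value < 0.01

    def test_variance_matches_placement_hand_computation(self):
        labels = np.array([1, 1, 1, 0, 0, 0, 0])
        a = np.array([0.9, 0.8, 0.4, 0.7, 0.3, 0.2, 0.1])
        b = np.array([0.6, 0.5, 0.9, 0.4, 0.8, 0.3, 0.2])
        ra, rb = roc_youden(a, labels), roc_youden(b, labels)
        res = compare_auc(ra, rb)

        def placements(scores):
            pos, neg = scores[labels == 1], scores[labels == 0]
            v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
            v01 = np.array([np.mean((pos > q) + 0.5 * (pos == q)) for q in neg])
            return v10, v01

        v10a, v01a = placements(a)
        v10b, v01b = placements(b)
        s10 = np.cov(np.vstack([v10a, v10b]))
        s01 = np.cov(np.vstack([v01a, v01b]))
        var = (s10 / 3 + s01 / 4)[0, 0] + (s10 / 3 + s01 / 4)[1, 1] - 2 * (s10 / 3 + s01 / 4)[0, 1]
        z_oracle = (ra.auc - rb.auc) / math.sqrt(var)
        assert res.statistic == pytest.approx(z_oracle, abs=1e-10)

    def test_unpaired_inputs_rejected(self, rng):
        l1 = np.repeat([0, 1], 5)
        l2 = np.repeat([0, 1], 6)
        r1 = roc_youden(rng.standard_normal(10), l1)
        r2 = roc_youden(rng.standard_normal(12), l2)
        with pytest.raises(DataError):
            compare_auc(r1, r2)


class TestSampleSize:
    @pytest.mark.parametrize(
        "r2,k,expected",
        [(0.964, 5, 8), (0.960, 11, 14)],
    )
    def test_regression_power_reference_values(self, r2, k, expected):
        assert regression_sample_size(r2, k, power=0.80, alpha=0.05) == expected

    @pytest.mark.parametrize("r2,k", [(0.3, 3), (0.8, 6), (0.05, 2)])
    def test_returned_n_respects_df_constraint(self, r2, k):
        n = regression_sample_size(r2, k, power=0.80, alpha=0.05)
        assert n >= k + 2
        # minimality: n - 1 must fail to reach the power (or hit the df floor)
        if n > k + 2:
            f2 = r2 / (1 - r2)
            df2 = (n - 1) - k - 1
            fcrit = stats.f.isf(0.05, k, df2)
            assert stats.ncf.sf(fcrit, k, df2, f2 * (n - 1)) < 0.80

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            regression_sample_size(1.2, 3)
        with pytest.raises(ValueError):
            regression_sample_size(0.5, 0)


def test_normality_wrapper(rng):
    res = normality_test(rng.standard_normal(200))
    assert 0 <= res.p_value <= 1 and res.test_name == "Shapiro-Wilk"


class TestTimingHarness:
    def test_empty_epoch_list(self):
        rep = timing_harness(lambda i: None, lambda m, i: None, epochs=[])
        assert rep.summary()["train_s"]["n"] == 0

    def test_epoch_sample_count_at_2048hz(self):
        rep = timing_harness(lambda i: None, lambda m, i: None, epochs=[], epoch_ms=250, fs=2048)
        assert rep.samples_per_epoch == 512

    def test_timings_positive(self, rng):
        idx = [np.arange(512)] * 5
        rep = timing_harness(lambda i: float(np.sum(i)), lambda m, i: m, epochs=idx)
        assert np.all(rep.train_times_s > 0) and np.all(rep.test_times_s > 0)
        s = rep.summary()
        assert s["train_s"]["n"] == 5 and s["train_s"]["mean"] > 0
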