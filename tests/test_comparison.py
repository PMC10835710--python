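"""Bias, variance, limits-of-agreement and repeatability statistics.

Hand-computed expected values come from the closed-form t / F / chi-square
formulas evaluated independently (frozen below); distributional properties
are checked against seeded simulation.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phenocompare import (
    InsufficientDataError,
    SimConfig,
    ValidationError,
    VarianceEstimate,
    coefficient_of_repeatability,
    compare_methods,
    compare_variances,
    estimate_bias,
    homogeneity_check,
    limits_of_agreement,
    pool_variances,
    replicate_correlation,
    simulate_repeated_measures,
    within_subject_variances,
)
from conftest import table_from_subject_values


class TestEstimateBias:
    def test_identical_subject_means_give_zero_bias(self):
        t = table_from_subject_values(
            {("s1", "A"): [1, 3], ("s1", "B"): [2, 2],
             ("s2", "A"): [4, 6], ("s2", "B"): [5, 5]}
        )
        r = estimate_bias(t, "A", "B")
        assert r.b_hat == 0.0 and r.t_stat == 0.0
        assert not r.significant

    def test_hand_computed_one_sample_t(self):
        # per-subject differences {1, 2, 3}: mean 2, se = 1/sqrt(3), t = 2*sqrt(3)
        t = table_from_subject_values(
            {("s1", "A"): [0, 0], ("s1", "B"): [1, 1],
             ("s2", "A"): [0, 0], ("s2", "B"): [2, 2],
             ("s3", "A"): [0, 0], ("s3", "B"): [3, 3]}
        )
        r = estimate_bias(t, "A", "B")
        assert r.b_hat == pytest.approx(2.0)
        assert r.se == pytest.approx(0.57735, abs=1e-4)
        assert r.t_stat == pytest.approx(3.4641, abs=1e-3)
        assert r.df == 2
        assert r.p_value == pytest.approx(0.0742, abs=1e-3)

    def test_two_sample_mode_matches_reference(self):
        rng = np.random.default_rng(5)
        vals = {}
        for j in range(6):
            vals[(f"s{j}", "A")] = rng.normal(10, 1, 3)
            vals[(f"s{j}", "B")] = rng.normal(11, 1, 3)
        t = table_from_subject_values(vals)
        r = estimate_bias(t, "A", "B", mode="two-sample")
        ma = t.subject_means("A").to_numpy()
        mb = t.subject_means("B").to_numpy()
        ref = stats.ttest_ind(mb, ma, equal_var=True)
        assert r.t_stat == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)
        assert r.df == 10

    def test_requires_two_shared_subjects(self):
        t = table_from_subject_values({("s1", "A"): [1, 2], ("s1", "B"): [1, 2]})
        with pytest.raises(InsufficientDataError):
            estimate_bias(t, "A", "B")

    def test_degenerate_nonzero_mean_flags_limiting_p(self):
        t = table_from_subject_values(
            {("s1", "A"): [0, 0], ("s1", "B"): [1, 1],
             ("s2", "A"): [0, 0], ("s2", "B"): [1, 1]}
        )
        with pytest.warns(UserWarning, match="limiting"):
            r = estimate_bias(t, "A", "B")
        assert r.degenerate and r.p_value == 0.0


class TestWithinSubjectVariances:
    def test_constant_replicates(self):
        t = table_from_subject_values({("s1", "A"): [5, 5, 5]})
        (v,) = within_subject_variances(t, "A")
        assert v.sigma2_hat == 0.0 and v.df == 2

    def test_hand_arithmetic(self):
        t = table_from_subject_values({("s1", "A"): [1, 2, 3, 4, 5]})
        (v,) = within_subject_variances(t, "A")
        assert v.sigma2_hat == pytest.approx(2.5)
        assert v.df == 4

    def test_chi_square_ci(self):
        # s2 = 2, df = 4: CI = (8/11.1433, 8/0.48442) = (0.7179, 16.514)
        t = table_from_subject_values({("s1", "A"): [0, 1, 2, 3, 4]})
        (v,) = within_subject_variances(t, "A", conf_level=0.95)
        assert v.sigma2_hat == pytest.approx(2.5)
        scale = 2.5 / 2.0
        assert v.ci_lower == pytest.approx(0.7179 * scale, abs=2e-3)
        assert v.ci_upper == pytest.approx(16.514 * scale, abs=2e-2)
        assert v.ci_lower <= v.sigma2_hat <= v.ci_upper

    def test_single_replicate_excluded_with_warning(self):
        t = table_from_subject_values({("s1", "A"): [1.0], ("s2", "A"): [1, 2]})
        with pytest.warns(UserWarning, match="excluded"):
            vs = within_subject_variances(t, "A")
        assert [v.subject_id for v in vs] == ["s2"]
        with pytest.raises(InsufficientDataError):
            within_subject_variances(t, "A", strict=True)


class TestCompareVariances:
    def _ve(self, s2, df, method="A", subject="s"):
        return VarianceEstimate(sigma2_hat=s2, df=df, subject_id=subject, method_id=method)

    def test_equal_variances(self):
        r = compare_variances(self._ve(2.0, 4), self._ve(2.0, 4, "B"))
        assert r.f_ratio == 1.0 and r.p_value == 1.0
        assert r.larger_method == "none"

    def test_f_cdf_oracle(self):
        # F = 4 on (4, 4): upper tail = 1 - I_{0.8}(2, 2) = 1 - (3*0.8^2 - 2*0.8^3)
        # = 0.104, so the two-tailed p = 0.208 (closed-form incomplete beta)
        r = compare_variances(self._ve(4.0, 4), self._ve(1.0, 4, "B"))
        assert r.f_ratio == pytest.approx(4.0)
        assert r.p_value == pytest.approx(0.208, abs=1e-3)

    def test_zero_denominator_limiting(self):
        r = compare_variances(self._ve(1.0, 4), self._ve(0.0, 4, "B"))
        assert r.infinite_ratio and r.p_value == 0.0 and r.significant

    def test_both_zero_indeterminate(self):
        with pytest.raises(ValidationError, match="indeterminate"):
            compare_variances(self._ve(0.0, 4), self._ve(0.0, 4, "B"))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        s2a=st.floats(0.01, 100), s2b=st.floats(0.01, 100),
        dfa=st.integers(1, 40), dfb=st.integers(1, 40),
    )
    def test_symmetry_under_method_swap(self, s2a, s2b, dfa, dfb):
        r1 = compare_variances(self._ve(s2a, dfa), self._ve(s2b, dfb, "B"))
        r2 = compare_variances(self._ve(s2b, dfb, "B"), self._ve(s2a, dfa))
        assert r1.f_ratio == pytest.approx(1.0 / r2.f_ratio)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)


class TestPoolVariances:
    def _ve(self, s2, df):
        return VarianceEstimate(sigma2_hat=s2, df=df, subject_id="s", method_id="A")

    @pytest.mark.parametrize(
        "pairs, expected_s2, expected_df",
        [
            ([(2, 1), (4, 3)], 3.5, 4),
            ([(1, 4), (9, 4)], 5.0, 8),
            ([(7, 2), (7, 5), (7, 9)], 7.0, 16),
        ],
    )
    def test_df_weighted_pooling(self, pairs, expected_s2, expected_df):
        pooled = pool_variances([self._ve(s2, df) for s2, df in pairs])
        assert pooled.sigma2_hat == pytest.approx(expected_s2)
        assert pooled.df == expected_df
        assert pooled.subject_id == "pooled"

    def test_equal_df_equals_plain_average(self):
        rng = np.random.default_rng(0)
        s2s = rng.uniform(0.1, 5.0, 8)
        pooled = pool_variances([self._ve(s2, 3) for s2 in s2s])
        assert pooled.sigma2_hat == pytest.approx(s2s.mean())

    def test_empty_list_errors(self):
        with pytest.raises(InsufficientDataError):
            pool_variances([])

    def test_cross_method_pooling_rejected(self):
        a = VarianceEstimate(1.0, 2, "s", "A")
        b = VarianceEstimate(1.0, 2, "s", "B")
        with pytest.raises(ValidationError):
            pool_variances([a, b])


class TestLimitsOfAgreement:
    def test_zero_spread(self):
        t = table_from_subject_values(
            {("s1", "A"): [1, 2], ("s1", "B"): [4, 5],
             ("s2", "A"): [1, 2], ("s2", "B"): [4, 5]}
        )
        r = limits_of_agreement(t, "A", "B", k_multiplier=1.96)
        assert r.loa_lower == r.loa_upper == pytest.approx(3.0)

    def test_hand_arithmetic(self):
        # differences {-1, 1, -1, 1}: mean 0, sd = sqrt(4/3), LOA = +/-2.2632
        t = table_from_subject_values(
            {("s1", "A"): [0, 0], ("s1", "B"): [-1, 1],
             ("s2", "A"): [0, 0], ("s2", "B"): [-1, 1]}
        )
        r = limits_of_agreement(t, "A", "B", k_multiplier=1.96)
        assert r.mean_diff == pytest.approx(0.0)
        assert r.sd_diff == pytest.approx(1.1547, abs=1e-4)
        assert r.loa_lower == pytest.approx(-2.2632, abs=1e-3)
        assert r.loa_upper == pytest.approx(2.2632, abs=1e-3)
        assert r.n_differences == 4

    def test_unequal_counts_suggest_subject_means(self):
        t = table_from_subject_values(
            {("s1", "A"): [1, 2, 3], ("s1", "B"): [1, 2],
             ("s2", "A"): [1, 2], ("s2", "B"): [1, 2]}
        )
        with pytest.raises(ValidationError, match="subject-means"):
            limits_of_agreement(t, "A", "B", pairing="replicate-index")
        r = limits_of_agreement(t, "A", "B", pairing="subject-means")
        assert r.n_differences == 2

    def test_threshold_verdict(self):
        t = table_from_subject_values(
            {("s1", "A"): [0, 0], ("s1", "B"): [-1, 1],
             ("s2", "A"): [0, 0], ("s2", "B"): [-1, 1]}
        )
        wide = limits_of_agreement(t, "A", "B", k_multiplier=1.96, threshold=5.0)
        tight = limits_of_agreement(t, "A", "B", k_multiplier=1.96, threshold=2.0)
        assert wide.within_threshold is True
        assert tight.within_threshold is False


class TestCoefficientOfRepeatability:
    def test_identical_replicates(self):
        t = table_from_subject_values({("s1", "A"): [3, 3], ("s2", "A"): [5, 5]})
        assert coefficient_of_repeatability(t, "A") == 0.0

    def test_conventions(self):
        # differences {2, -2, 2, -2}: sample sd = sqrt(16/3) -> CR 4.6188;
        # zero-mean sd = 2 -> CR 4
        t = table_from_subject_values(
            {("s1", "A"): [2, 0], ("s2", "A"): [0, 2],
             ("s3", "A"): [2, 0], ("s4", "A"): [0, 2]}
        )
        assert coefficient_of_repeatability(t, "A", "sample-sd") == pytest.approx(4.6188, abs=1e-3)
        assert coefficient_of_repeatability(t, "A", "zero-mean-sd") == pytest.approx(4.0)

    def test_extra_replicates_warn_and_use_first_two(self):
        t = table_from_subject_values({("s1", "A"): [1, 3, 100]})
        with pytest.warns(UserWarning, match="first two"):
            cr = coefficient_of_repeatability(t, "A", "zero-mean-sd")
        assert cr == pytest.approx(4.0)

    def test_no_replicates_errors(self):
        t = table_from_subject_values({("s1", "A"): [1.0]})
        with pytest.raises(InsufficientDataError):
            coefficient_of_repeatability(t, "A")


class TestReplicateCorrelation:
    def test_identical_methods_r_one(self, two_method_table):
        t = table_from_subject_values(
            {("s1", "A"): [1, 2], ("s1", "B"): [1, 2],
             ("s2", "A"): [5, 6], ("s2", "B"): [5, 6]}
        )
        for seed in (0, 1, 99):
            assert replicate_correlation(t, "A", "B", seed=seed) == pytest.approx(1.0)

    def test_negated_methods_r_minus_one(self):
        t = table_from_subject_values(
            {("s1", "A"): [1, 2], ("s1", "B"): [-1, -2],
             ("s2", "A"): [5, 6], ("s2", "B"): [-5, -6]}
        )
        assert replicate_correlation(t, "A", "B", seed=0) == pytest.approx(-1.0)

    def test_deterministic_given_seed(self, two_method_table):
        r1 = replicate_correlation(two_method_table, "A", "B", seed=42)
        r2 = replicate_correlation(two_method_table, "A", "B", seed=42)
        assert r1 == r2

    def test_zero_variance_errors(self):
        t = table_from_subject_values(
            {("s1", "A"): [1, 1], ("s1", "B"): [1, 2],
             ("s2", "A"): [1, 1], ("s2", "B"): [3, 4]}
        )
        with pytest.raises(ValidationError, match="undefined"):
            replicate_correlation(t, "A", "B", seed=0)


class TestHomogeneityCheck:
    def test_constant_variances_recommend_pool(self):
        rec, diag = homogeneity_check([2.0] * 6, [1, 2, 3, 4, 5, 6])
        assert rec == "pool"
        assert diag["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_planted_trend_recommends_per_subject(self):
        means = np.linspace(1, 10, 10)
        rec, diag = homogeneity_check(0.5 * means, means)
        assert rec == "per-subject"
        assert diag["slope"] > 0

    def test_too_few_subjects(self):
        with pytest.raises(InsufficientDataError):
            homogeneity_check([1.0, 2.0], [1.0, 2.0])


class TestCompareMethods:
    def test_identical_synthetic_methods_equally_precise(self):
        cfg = SimConfig(
            mu=np.linspace(5, 15, 12),
            bias={"A": 0.0, "B": 0.0},
            sigma={"A": 1.0, "B": 1.0},
            replicates=4,
            seed=123,
        )
        table = simulate_repeated_measures(cfg)
        report = compare_methods(table, "A", "B", seed=0)
        assert not report.verdict.biased
        assert report.verdict.precision == "equally_precise"
        assert "unbiased" in report.verdict.summary

    def test_mean_dependent_variance_triggers_per_subject_f_tests(self):
        # method A's spread grows with the subject mean and dwarfs B's:
        # auto pooling must switch to per-subject and call B more precise
        cfg = SimConfig(
            mu=np.linspace(1, 30, 25),
            bias={"A": 0.0, "B": 0.0},
            sigma={"A": (0.05, 0.3), "B": 0.02},
            replicates=5,
            seed=7,
        )
        table = simulate_repeated_measures(cfg)
        report = compare_methods(table, "A", "B", seed=0)
        assert report.pooling == "per-subject"
        assert report.pooled_comparison is None
        assert report.verdict.precision == "b_more_precise"
        assert report.verdict.n_subjects_a_larger > report.verdict.n_subjects_b_larger

    def test_verdict_deterministic(self, pefr):
        r1 = compare_methods(pefr, "wright", "mini", seed=3)
        r2 = compare_methods(pefr, "wright", "mini", seed=3)
        assert r1.verdict == r2.verdict
        assert r1.correlation == r2.correlation


class TestCalibration:
    def test_bias_recovery_within_three_se(self):
        cfg = SimConfig(
            mu=np.linspace(0, 10, 200),
            bias={"A": 0.0, "B": 0.5},
            sigma={"A": 1.0, "B": 1.0},
            replicates=5,
            seed=2024,
        )
        table = simulate_repeated_measures(cfg)
        r = estimate_bias(table, "A", "B")
        assert abs(r.b_hat - 0.5) < 3 * r.se

    def test_chi_square_ci_nominal_coverage(self):
        # 95% CI coverage over many simulated within-subject variances
        from phenocompare.comparison import variance_ci

        rng = np.random.default_rng(99)
        df, sigma2, reps = 4, 2.0, 20_000
        s2 = sigma2 * rng.chisquare(df, reps) / df
        unit_lo, unit_hi = variance_ci(1.0, df)  # CI scales linearly in s2
        covered = (unit_lo * s2 <= sigma2) & (sigma2 <= unit_hi * s2)
        assert abs(covered.mean() - 0.95) < 0.01
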