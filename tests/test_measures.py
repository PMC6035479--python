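"""Closed-form reference effect measures and comparison measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from remvar import (
    EffectScale,
    EmpiricalRiskDistribution,
    LogGammaRandomEffect,
    NormalRandomEffect,
    UserQuantileRandomEffect,
    icc_latent,
    iom,
    mor,
    mor_percentile,
    per_sd,
    percentile_equivalent,
    rem_empirical,
    rem_empirical_range,
    rem_random,
    rem_range,
    sigma_from_rem,
)

SIGMA_EX1 = 0.511  # published hospital random-effect SD, rhythm-control model


class TestRemRandom:
    @pytest.mark.parametrize(
        "sigma,a,expected,decimals",
        [
            (SIGMA_EX1, 0.025, 0.367, 3),
            (SIGMA_EX1, 0.75, 1.41, 2),
            (SIGMA_EX1, 0.975, 2.72, 2),
        ],
    )
    def test_published_values(self, sigma, a, expected, decimals):
        assert round(rem_random(sigma, a), decimals) == expected

    def test_median_is_unity(self):
        for sigma in (0.0, 0.3, 2.0):
            assert rem_random(sigma, 0.5) == pytest.approx(1.0, abs=1e-15)

    def test_difference_scale_is_linear_predictor_shift(self):
        val = rem_random(0.4, 0.8, EffectScale.DIFFERENCE)
        assert val == pytest.approx(0.4 * stats.norm.ppf(0.8))

    @pytest.mark.parametrize("a", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_out_of_range_percentile(self, a):
        with pytest.raises(ValueError):
            rem_random(0.5, a)

    @given(st.floats(0.01, 3.0), st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_reciprocal_symmetry(self, sigma, a):
        assert rem_random(sigma, a) * rem_random(sigma, 1.0 - a) == pytest.approx(
            1.0, rel=1e-12
        )


class TestRemRange:
    def test_published_95_range(self):
        lo, hi = rem_range(SIGMA_EX1, 0.95)
        assert (round(lo, 2), round(hi, 2)) == (0.37, 2.72)

    def test_zero_sigma_collapses_to_unity(self):
        assert rem_range(0.0, 0.95) == (1.0, 1.0)

    def test_80_level_closed_form(self):
        lo, hi = rem_range(0.3, 0.80)
        q = stats.norm.ppf(0.90)
        assert lo == pytest.approx(np.exp(-0.3 * q))
        assert hi == pytest.approx(np.exp(0.3 * q))

    def test_level_widens_range(self):
        w = [np.diff(rem_range(0.5, lv))[0] for lv in (0.5, 0.8, 0.95, 0.99)]
        assert np.all(np.diff(w) > 0)


class TestPercentileEquivalent:
    def test_published_chf_percentile(self):
        p = percentile_equivalent(0.409, NormalRandomEffect(SIGMA_EX1))
        assert round(100 * p) == 79

    def test_null_effect_maps_to_median(self):
        assert percentile_equivalent(0.0, NormalRandomEffect(0.5)) == pytest.approx(0.5)

    def test_one_sd_effect_maps_to_phi_one(self):
        p = percentile_equivalent(0.7, NormalRandomEffect(0.7))
        assert p == pytest.approx(stats.norm.cdf(1.0))

    def test_negative_effect_below_median(self):
        assert percentile_equivalent(-0.2, NormalRandomEffect(0.5)) < 0.5

    def test_boundary_sigma_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            percentile_equivalent(0.3, NormalRandomEffect(0.0))

    def test_numeric_inversion_for_user_quantile(self):
        dist = UserQuantileRandomEffect(lambda a: 0.5 * stats.norm.ppf(a))
        p = percentile_equivalent(0.5 * stats.norm.ppf(0.8), dist)
        assert p == pytest.approx(0.8, abs=1e-9)

    def test_out_of_support_inversion_rejected(self):
        dist = UserQuantileRandomEffect(lambda a: 0.5 * stats.norm.ppf(a))
        with pytest.raises(ValueError, match="support"):
            percentile_equivalent(100.0, dist)


class TestEmpiricalRem:
    def test_four_point_toy_under_linear_interpolation(self):
        # type-7 quantiles: q(0.975) = log 2, q(0.5) = 0.5 log 2, so the
        # median-centered ratio is exp(0.5 log 2) = sqrt(2)
        dist = EmpiricalRiskDistribution(np.array([0.0, 0.0, np.log(2), np.log(2)]))
        assert rem_empirical(dist, 0.975) == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_median_is_unity(self):
        dist = EmpiricalRiskDistribution(np.array([-1.0, 0.3, 0.7, 2.0]))
        assert rem_empirical(dist, 0.5) == pytest.approx(1.0)

    def test_degenerate_values_give_unity_everywhere(self):
        dist = EmpiricalRiskDistribution(np.full(10, 1.7))
        for a in (0.025, 0.3, 0.5, 0.9, 0.975):
            assert rem_empirical(dist, a) == pytest.approx(1.0)
        assert rem_empirical_range(dist, 0.95) == (1.0, 1.0)

    def test_five_point_range_matches_bruteforce_quantiles(self):
        vals = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        dist = EmpiricalRiskDistribution(vals)
        lo, hi = rem_empirical_range(dist, 0.95)
        # hand-computed type-7: h = 4a; q(0.025) = -0.95, q(0.975) = 0.95
        assert lo == pytest.approx(np.exp(-0.95))
        assert hi == pytest.approx(np.exp(0.95))

    def test_large_normal_sample_converges_to_closed_form(self):
        rng = np.random.default_rng(5)
        s = 0.7
        dist = EmpiricalRiskDistribution(rng.normal(0.0, s, size=100_000))
        for a in (0.1, 0.75, 0.975):
            expected = np.exp(s * stats.norm.ppf(a))
            assert rem_empirical(dist, a) == pytest.approx(expected, rel=0.03)

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(0)
        dist = EmpiricalRiskDistribution(rng.normal(size=500))
        grid = np.linspace(0.01, 0.99, 33)
        vals = [rem_empirical(dist, a) for a in grid]
        assert np.all(np.diff(vals) >= 0)

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError):
            EmpiricalRiskDistribution(np.array([]))

    def test_nonfinite_values_rejected(self):
        with pytest.raises(ValueError):
            EmpiricalRiskDistribution(np.array([0.0, np.inf]))


class TestIom:
    def test_published_lower_endpoint(self):
        # median-age CHF patient, all other covariates zero
        assert round(iom(-2.292 + 0.409, SIGMA_EX1, 0.025) * 100, 1) == 5.3

    def test_median_cluster_null_pattern(self):
        assert iom(0.0, 0.5, 0.5) == pytest.approx(0.5)

    def test_monotone_in_percentile(self):
        grid = np.linspace(0.01, 0.99, 25)
        vals = [iom(-1.0, 0.5, a) for a in grid]
        assert np.all(np.diff(vals) > 0)

    def test_non_logit_family_rejected(self):
        with pytest.raises(ValueError, match="binomial"):
            iom(0.0, 0.5, 0.5, family="poisson")


class TestComparisonMeasures:
    def test_published_mor(self):
        assert round(mor(SIGMA_EX1), 2) == 1.63

    def test_published_per_sd(self):
        assert round(per_sd(SIGMA_EX1), 2) == 1.67

    def test_published_icc(self):
        assert round(icc_latent(SIGMA_EX1), 3) == 0.074

    def test_example2_chain_from_published_rem(self):
        sigma = sigma_from_rem(1.29, 0.975)
        assert round(mor(sigma), 2) == 1.13
        assert round(icc_latent(sigma), 3) == 0.005

    def test_null_values_at_zero_sigma(self):
        assert mor(0.0) == 1.0
        assert per_sd(0.0) == 1.0
        assert icc_latent(0.0) == 0.0

    @pytest.mark.parametrize("fn", [mor, per_sd, icc_latent])
    def test_negative_sigma_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(-0.1)

    @pytest.mark.parametrize("sigma", [0.01, 0.1, 0.5, 1.0, 2.0])
    def test_mor_and_per_sd_are_rem_values(self, sigma):
        assert mor(sigma) == pytest.approx(
            rem_random(sigma, mor_percentile()), rel=1e-12
        )
        assert per_sd(sigma) == pytest.approx(
            rem_random(sigma, stats.norm.cdf(1.0)), rel=1e-12
        )

    def test_mor_percentile_value(self):
        assert round(mor_percentile(), 2) == 0.83

    def test_icc_strictly_increasing_and_bounded(self):
        grid = np.linspace(0.0, 5.0, 50)
        vals = np.array([icc_latent(s) for s in grid])
        assert np.all(np.diff(vals) > 0)
        assert vals[0] == 0.0 and vals[-1] < 1.0


class TestSigmaFromRem:
    def test_published_example2_inversion(self):
        assert sigma_from_rem(1.29, 0.975) == pytest.approx(0.1299, abs=5e-4)

    def test_unity_rem_gives_zero_sigma(self):
        assert sigma_from_rem(1.0, 0.8) == 0.0

    @given(st.floats(0.05, 3.0), st.floats(0.55, 0.99))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip(self, sigma, a):
        v = rem_random(sigma, a)
        assert sigma_from_rem(v, a) == pytest.approx(sigma, rel=1e-12)

    def test_median_percentile_rejected(self):
        with pytest.raises(ValueError):
            sigma_from_rem(1.3, 0.5)


class TestNonNormalRandomEffects:
    def test_log_gamma_is_median_centered(self):
        dist = LogGammaRandomEffect(shape=2.0)
        assert dist.quantile(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_log_gamma_left_skew_on_log_scale(self):
        dist = LogGammaRandomEffect(shape=2.0)
        # lower tail stretches further than the upper tail
        assert -dist.quantile(0.025) > dist.quantile(0.975)

    def test_rem_uses_centered_quantiles(self):
        dist = LogGammaRandomEffect(shape=2.0)
        assert rem_random(dist, 0.5) == pytest.approx(1.0)
        assert rem_random(dist, 0.9) == pytest.approx(np.exp(dist.quantile(0.9)))

    def test_quantile_nondecreasing(self):
        dist = LogGammaRandomEffect(shape=1.5)
        grid = np.linspace(0.01, 0.99, 40)
        q = [dist.quantile(a) for a in grid]
        assert np.all(np.diff(q) >= 0)
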