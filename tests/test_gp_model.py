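"""Generalized Poisson observation model and posterior machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson

from cornas import (
    CoverageError,
    GPParams,
    GPValidityWarning,
    ParameterError,
    gp_pmf,
    mean_variance_ratio,
    posterior_gamma,
    posterior_percentile,
    posterior_pmf_bruteforce,
)


class TestGPPmf:
    def test_reduces_to_poisson_at_m_equal_one(self):
        """With m=1 (lambda2=0) the GP is exactly Poisson with mean b*k."""
        params = GPParams.from_coverage(0.5, 10, m=1.0)
        assert params.lambda2 == 0.0
        x = np.arange(51)
        np.testing.assert_allclose(
            gp_pmf(x, params), poisson.pmf(x, 5.0), atol=1e-12
        )
        assert gp_pmf(5, params) == pytest.approx(0.17546736976785070, rel=1e-12)

    def test_zero_count_is_exp_minus_lambda1(self):
        params = GPParams.from_coverage(0.3, 50)
        assert gp_pmf(0, params) == pytest.approx(math.exp(-params.lambda1), rel=1e-12)

    def test_high_precision_regression_value(self):
        # frozen from a 50-digit symbolic evaluation of the pmf at
        # b=0.25, k=100, m=1/(1-0.25), x=25
        params = GPParams.from_coverage(0.25, 100)
        assert params.m == pytest.approx(4.0 / 3.0, rel=1e-15)
        assert gp_pmf(25, params) == pytest.approx(0.091825194873682261, rel=1e-10)

    def test_underdispersed_pmf_zero_outside_support(self):
        # lambda2 < 0: the pmf vanishes where lambda1 + x*lambda2 <= 0
        params = GPParams.from_coverage(0.5, 4)  # lambda1=2.83, lambda2=-0.41
        x_big = int(np.ceil(params.lambda1 / -params.lambda2)) + 1
        assert gp_pmf(x_big, params) == 0.0
        assert gp_pmf(1, params) > 0.0

    def test_pmf_sums_to_at_most_one(self):
        params = GPParams.from_coverage(0.25, 200)
        total = gp_pmf(np.arange(2000), params).sum()
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_moments_match_coverage_times_count(self):
        params = GPParams.from_coverage(0.4, 123)
        assert params.mean == pytest.approx(0.4 * 123, rel=1e-12)
        assert params.variance == pytest.approx(0.4 * 123 / params.m, rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            GPParams(lambda1=-1.0, lambda2=0.0, m=1.0, b=0.5, k=10)
        with pytest.raises(ParameterError):
            GPParams.from_coverage(0.5, 0)
        with pytest.raises(ParameterError):
            gp_pmf(-1, GPParams.from_coverage(0.5, 10))


class TestMeanVarianceRatio:
    @pytest.mark.parametrize(
        "b,expected", [(0.5, 2.0), (0.25, 4.0 / 3.0), (0.4, 5.0 / 3.0)]
    )
    def test_values(self, b, expected):
        assert mean_variance_ratio(b) == pytest.approx(expected, rel=1e-12)

    def test_small_coverage_limit_is_one_plus_b(self):
        # for small b, m = 1/(1-b) ~= 1 + b
        for b in (1e-3, 1e-4):
            assert mean_variance_ratio(b) == pytest.approx(1.0 + b, abs=b * b * 2)

    @pytest.mark.parametrize("b", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, b):
        with pytest.raises(CoverageError):
            mean_variance_ratio(b)

    def test_warns_outside_gp_validity(self):
        with pytest.warns(GPValidityWarning):
            mean_variance_ratio(0.8)


class TestBruteForcePosterior:
    def test_probs_renormalised(self):
        post = posterior_pmf_bruteforce(7, 0.3)
        assert post.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(post.probs >= 0)
        assert post.truncation_mass_bound < 1e-10

    def test_support_starts_at_max_x_one(self):
        assert posterior_pmf_bruteforce(0, 0.4).support_min == 1
        assert posterior_pmf_bruteforce(12, 0.4).support_min == 12

    def test_mode_concentrates_near_x_over_b(self):
        # the posterior mode sits within 2 counts of x/b (E[X|T=k] = b*k);
        # offset constant fixed by scanning the exact posterior
        for b in (0.1, 0.25, 0.5):
            for x in (1, 10, 100):
                post = posterior_pmf_bruteforce(x, b)
                assert post.mode() >= x / b - 2

    def test_bad_tol_rejected(self):
        with pytest.raises(ParameterError):
            posterior_pmf_bruteforce(5, 0.3, tol=0.0)

    def test_high_coverage_warns_but_runs(self):
        with pytest.warns(GPValidityWarning):
            post = posterior_pmf_bruteforce(10, 0.8)
        assert post.probs.sum() == pytest.approx(1.0, abs=1e-12)


# Measured agreement between the gamma approximation and the exact
# posterior, frozen with headroom from a scan of the brute-force oracle.
# The closed-form moment formulas are fitted approximations: they are
# excellent for large x (mean error < 0.5%, TV < 0.05) but degrade at
# small observed counts, especially at high coverage.
GAMMA_VS_ORACLE_BOUNDS = {
    # (b, x): (max relative mean difference, max total variation distance)
    (0.1, 1): (0.06, 0.07),
    (0.1, 5): (0.02, 0.05),
    (0.1, 10): (0.015, 0.04),
    (0.1, 50): (0.005, 0.03),
    (0.1, 100): (0.005, 0.03),
    (0.1, 500): (0.005, 0.03),
    (0.25, 1): (0.13, 0.14),
    (0.25, 5): (0.04, 0.09),
    (0.25, 10): (0.025, 0.07),
    (0.25, 50): (0.005, 0.06),
    (0.25, 100): (0.005, 0.055),
    (0.25, 500): (0.005, 0.05),
    (0.5, 1): (0.24, 0.22),
    (0.5, 5): (0.06, 0.12),
    (0.5, 10): (0.035, 0.09),
    (0.5, 50): (0.01, 0.055),
    (0.5, 100): (0.005, 0.05),
    (0.5, 500): (0.005, 0.04),
}


class TestGammaApproximation:
    @pytest.mark.parametrize("x,b", [(0, 0.5), (100, 0.25)])
    def test_moment_formulas(self, x, b):
        pg = posterior_gamma(x, b)
        mu = (x + 1) / b - 1.0 / (1.0 + 1.0 / (2 * b))
        sigma2 = (x + 1) / (b * (b + 1)) ** 2
        assert pg.mu == pytest.approx(mu, rel=1e-12)
        assert pg.sigma2 == pytest.approx(sigma2, rel=1e-12)

    def test_printed_example_values(self):
        pg = posterior_gamma(0, 0.5)
        assert pg.mu == pytest.approx(1.5, rel=1e-12)
        assert pg.sigma2 == pytest.approx(1.7778, abs=5e-5)
        pg = posterior_gamma(100, 0.25)
        assert pg.mu == pytest.approx(403.6667, abs=5e-5)
        assert pg.sigma2 == pytest.approx(1034.24, abs=0.005)

    @pytest.mark.parametrize("bx", sorted(GAMMA_VS_ORACLE_BOUNDS))
    def test_agrees_with_bruteforce_oracle(self, bx):
        """Gamma approximation vs the exact posterior, within the frozen
        empirically measured bounds."""
        b, x = bx
        mean_bound, tv_bound = GAMMA_VS_ORACLE_BOUNDS[bx]
        post = posterior_pmf_bruteforce(x, b)
        pg = posterior_gamma(x, b)
        rel_mean = abs(pg.mu - post.mean()) / post.mean()
        assert rel_mean < mean_bound
        k = post.support
        gamma_pmf = pg.cdf(k + 0.5) - pg.cdf(k - 0.5)
        tv = 0.5 * (np.abs(post.probs - gamma_pmf).sum() + abs(1 - gamma_pmf.sum()))
        assert tv < tv_bound

    def test_mean_monotone_increasing_in_x(self):
        mus = [posterior_gamma(x, 0.3).mu for x in range(0, 200, 7)]
        assert np.all(np.diff(mus) > 0)

    def test_mean_monotone_decreasing_in_b(self):
        mus = [posterior_gamma(50, b).mu for b in np.linspace(0.05, 0.95, 19)]
        assert np.all(np.diff(mus) < 0)

    def test_domain_errors(self):
        with pytest.raises(CoverageError):
            posterior_gamma(10, 1.2)
        with pytest.raises(ParameterError):
            posterior_gamma(-1, 0.5)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        x=st.integers(min_value=0, max_value=100_000),
        b=st.floats(min_value=0.01, max_value=0.99),
    )
    def test_shape_scale_identities(self, x, b):
        pg = posterior_gamma(x, b)
        assert pg.mu > 0 and pg.sigma2 > 0
        assert pg.shape * pg.scale == pytest.approx(pg.mu, rel=1e-9)
        assert pg.shape * pg.scale**2 == pytest.approx(pg.sigma2, rel=1e-9)


class TestPercentiles:
    def test_median_below_mean_right_skew(self):
        pg = posterior_gamma(20, 0.3)
        assert posterior_percentile(pg, 0.5) < pg.mu

    def test_quantile_cdf_round_trip(self):
        pg = posterior_gamma(100, 0.25)
        for q in (0.005, 0.5, 0.995):
            assert pg.cdf(posterior_percentile(pg, q)) == pytest.approx(q, abs=1e-9)

    def test_strictly_increasing_in_q(self):
        pg = posterior_gamma(7, 0.2)
        qs = np.linspace(0.01, 0.99, 25)
        vals = [posterior_percentile(pg, q) for q in qs]
        assert np.all(np.diff(vals) > 0)

    def test_regression_constants_from_independent_oracle(self):
        # frozen from R stats::qgamma with the same shape/scale
        pg = posterior_gamma(100, 0.25)
        assert posterior_percentile(pg, 0.005) == pytest.approx(
            325.64335816371931, rel=1e-10
        )
        assert posterior_percentile(pg, 0.995) == pytest.approx(
            491.30826941720909, rel=1e-10
        )

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.5, 2.0])
    def test_quantile_domain(self, q):
        with pytest.raises(ParameterError):
            posterior_percentile(posterior_gamma(5, 0.3), q)
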