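"""Distribution-layer checks: densities, tails, moments, CP/DP conversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from snsurv.distributions import (
    GompertzParams,
    SkewNormalCP,
    SkewNormalDP,
    WeibullParams,
    cp_to_dp,
    dp_to_cp,
    gamma1_max,
    gompertz_mean,
    gompertz_pdf_sf_hazard,
    gompertz_rvs,
    mixture_rvs,
    sn_cdf,
    sn_mean_var,
    sn_pdf,
    sn_ppf,
    sn_rvs,
    sn_sf,
    weibull_mean,
    weibull_pdf_sf_hazard,
    weibull_rvs,
)


def _phi(x):
    return math.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)


def _Phi(x):
    return 0.5 * (1 + math.erf(x / math.sqrt(2)))


class TestSkewNormalDensity:
    def test_reduces_to_standard_normal_at_zero_shape(self):
        assert sn_pdf(0.0, SkewNormalDP(0, 1, 0)) == pytest.approx(1 / math.sqrt(2 * math.pi))

    def test_matches_direct_formula(self):
        # independent arithmetic through math.erf, not the scipy code path
        assert sn_pdf(1.0, SkewNormalDP(0, 1, 3)) == pytest.approx(
            2 * _phi(1.0) * _Phi(3.0), rel=1e-12
        )

    @pytest.mark.parametrize("psi", [-5.0, -1.0, 0.0, 0.7, 4.0])
    def test_normalizes(self, psi):
        val, _ = integrate.quad(lambda y: sn_pdf(y, SkewNormalDP(0, 1, psi)), -12, 12)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_rejects_nonfinite_argument(self):
        with pytest.raises(ValueError):
            sn_pdf(np.inf, SkewNormalDP(0, 1, 1))

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            SkewNormalDP(0, -1, 0)


class TestSkewNormalCdf:
    def test_median_of_symmetric_case(self):
        assert sn_cdf(3.0, SkewNormalDP(3, 2, 0)) == pytest.approx(0.5)

    def test_complement(self):
        p = SkewNormalDP(1.0, 2.0, -1.3)
        y = np.linspace(-6, 9, 25)
        assert np.allclose(sn_cdf(y, p) + sn_sf(y, p), 1.0, atol=1e-12)

    def test_against_quadrature(self):
        p = SkewNormalDP(0, 1, 1)
        oracle, _ = integrate.quad(lambda y: sn_pdf(y, p), -12, 0.0)
        assert sn_cdf(0.0, p) == pytest.approx(oracle, abs=1e-10)

    def test_monotone_and_matches_library(self):
        p = SkewNormalDP(-1.0, 2.5, 2.0)
        y = np.linspace(-12, 12, 201)
        c = sn_cdf(y, p)
        assert np.all(np.diff(c) >= 0)
        # scipy.stats.skewnorm as an independent implementation
        ref = stats.skewnorm.cdf(y, p.psi, loc=p.xi, scale=p.sigma)
        assert np.allclose(c, ref, atol=1e-10)

    def test_sf_in_right_tail_via_quadrature(self, sn_dp):
        oracle, _ = integrate.quad(lambda y: sn_pdf(y, sn_dp), 90.0, 200.0)
        assert sn_sf(90.0, sn_dp) == pytest.approx(oracle, rel=1e-8)

    @pytest.mark.parametrize(
        "k, want",
        [(4, 1.6807239689382238e-85), (5, 2.850406013010672e-131)],
        ids=["4sigma", "5sigma"],
    )
    def test_negative_skew_deep_tail(self, sn_dp, k, want):
        # the plain Owen's-T expression cancels catastrophically here; the
        # quadrature fallback must recover the (arbitrary-precision) value
        val = sn_sf(sn_dp.xi + k * sn_dp.sigma, sn_dp)
        assert val == pytest.approx(want, rel=1e-9)

    def test_ppf_roundtrip(self):
        p = SkewNormalDP(2.0, 1.5, -2.0)
        q = np.array([0.01, 0.25, 0.5, 0.9, 0.99])
        assert np.allclose(sn_cdf(sn_ppf(q, p), p), q, atol=1e-9)


class TestSkewNormalMoments:
    def test_normal_case(self):
        assert sn_mean_var(SkewNormalDP(0, 1, 0)) == pytest.approx((0.0, 1.0))

    def test_half_normal_limit(self):
        mean, var = sn_mean_var(SkewNormalDP(0, 1, 1e9))
        assert mean == pytest.approx(math.sqrt(2 / math.pi), abs=1e-8)
        assert var == pytest.approx(1 - 2 / math.pi, abs=1e-8)

    def test_sampling_moments(self):
        p = SkewNormalDP(2.0, 3.0, -1.5)
        mean, var = sn_mean_var(p)
        x = sn_rvs(p, 1_000_000, np.random.default_rng(0))
        assert x.mean() == pytest.approx(mean, abs=3 * math.sqrt(var / x.size))
        assert x.var() == pytest.approx(var, rel=0.01)

    def test_rvs_deterministic_under_seed(self):
        p = SkewNormalDP(0, 1, 2)
        a = sn_rvs(p, 100, 42)
        b = sn_rvs(p, 100, 42)
        assert np.array_equal(a, b)

    def test_rvs_zero_shape_is_normal(self):
        x = sn_rvs(SkewNormalDP(0, 1, 0), 10_000, np.random.default_rng(3))
        skew = stats.skew(x)
        assert abs(skew) < 3 * math.sqrt(6 / x.size)

    def test_rvs_rejects_empty(self):
        with pytest.raises(ValueError):
            sn_rvs(SkewNormalDP(0, 1, 0), 0, 1)


class TestParametrizationConversion:
    def test_gaussian_fixed_point(self):
        cp = dp_to_cp(SkewNormalDP(0, 1, 0))
        assert (cp.mu, cp.s, cp.gamma1) == pytest.approx((0, 1, 0))

    def test_skewness_formula_at_unit_shape(self):
        got = dp_to_cp(SkewNormalDP(0, 1, 1)).gamma1
        want = 0.5 * (4 - math.pi) * (1 / (math.pi / 2 + (math.pi / 2 - 1))) ** 1.5
        assert got == pytest.approx(want, rel=1e-12)

    @pytest.mark.parametrize("psi", np.concatenate([np.linspace(-20, 20, 9), [0.01, -0.3]]))
    def test_roundtrip_dp_cp_dp(self, psi):
        p = SkewNormalDP(1.3, 2.7, float(psi))
        q = cp_to_dp(dp_to_cp(p))
        assert (q.xi, q.sigma, q.psi) == pytest.approx((p.xi, p.sigma, p.psi), abs=1e-8)

    def test_roundtrip_cp_dp_cp(self):
        c = SkewNormalCP(0.0, 1.0, 0.5)
        back = dp_to_cp(cp_to_dp(c))
        assert back.gamma1 == pytest.approx(0.5, abs=1e-10)

    def test_study_truth_consistency(self, sn_cp, sn_dp):
        mean, var = sn_mean_var(sn_dp)
        assert mean == pytest.approx(sn_cp.mu, abs=1e-10)
        assert math.sqrt(var) == pytest.approx(sn_cp.s, abs=1e-10)

    def test_boundary_is_shape_limit(self):
        # the admissible-skewness bound is the psi -> inf limit of gamma1
        assert dp_to_cp(SkewNormalDP(0, 1, 1e9)).gamma1 == pytest.approx(
            gamma1_max(), abs=1e-6
        )
        assert gamma1_max() == pytest.approx(0.99527, abs=1e-5)

    def test_out_of_range_skewness_rejected(self):
        with pytest.raises(ValueError):
            cp_to_dp(SkewNormalCP(0, 1, 0.999))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-15, 15), st.floats(0.1, 50), st.floats(-10, 10))
    def test_roundtrip_property(self, xi, sigma, psi):
        p = SkewNormalDP(xi, sigma, psi)
        q = cp_to_dp(dp_to_cp(p))
        assert math.isclose(q.xi, p.xi, abs_tol=1e-7 * max(1, abs(xi)))
        assert math.isclose(q.sigma, p.sigma, rel_tol=1e-7)


class TestGompertz:
    def test_at_origin(self, gomp):
        pdf, sf, hz = gompertz_pdf_sf_hazard(0.0, gomp)
        assert (sf, hz) == pytest.approx((1.0, gomp.alpha))

    def test_normalizes(self, gomp):
        val, _ = integrate.quad(lambda t: gompertz_pdf_sf_hazard(t, gomp)[0], 0, 150)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_survival_closed_form(self, gomp):
        a, g, t = gomp.alpha, gomp.gamma, 82.1
        want = math.exp(-(a / g) * (math.exp(g * t) - 1))
        assert gompertz_pdf_sf_hazard(t, gomp)[1] == pytest.approx(want, rel=1e-12)

    def test_mean_against_quadrature(self, gomp):
        oracle, _ = integrate.quad(lambda t: gompertz_pdf_sf_hazard(t, gomp)[1], 0, 200)
        assert gompertz_mean(gomp) == pytest.approx(oracle, rel=1e-8)

    def test_sampling_matches_mean(self, gomp):
        x = gompertz_rvs(gomp, 200_000, np.random.default_rng(1))
        assert x.mean() == pytest.approx(gompertz_mean(gomp), abs=3 * x.std() / math.sqrt(x.size))

    def test_negative_time_rejected(self, gomp):
        with pytest.raises(ValueError):
            gompertz_pdf_sf_hazard(-1.0, gomp)


class TestWeibull:
    def test_unit_shape_is_exponential(self):
        p = WeibullParams(alpha=10.0, gamma=1.0)
        pdf, sf, hz = weibull_pdf_sf_hazard(5.0, p)
        assert hz == pytest.approx(0.1)
        assert sf == pytest.approx(math.exp(-0.5))

    def test_scale_property(self):
        for g in (0.5, 1.0, 4.36):
            assert weibull_pdf_sf_hazard(53.83, WeibullParams(53.83, g))[1] == pytest.approx(
                math.exp(-1)
            )

    def test_hazard_closed_form(self):
        p = WeibullParams(alpha=53.83, gamma=4.36)
        want = (4.36 / 53.83) * (50 / 53.83) ** 3.36
        assert weibull_pdf_sf_hazard(50.0, p)[2] == pytest.approx(want, rel=1e-12)

    def test_mean_matches_sampling(self):
        p = WeibullParams(alpha=53.83, gamma=4.36)
        x = weibull_rvs(p, 200_000, np.random.default_rng(2))
        assert x.mean() == pytest.approx(weibull_mean(p), abs=3 * x.std() / math.sqrt(x.size))

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            weibull_pdf_sf_hazard(0.0, WeibullParams(1, 2))


class TestMixture:
    def test_degenerate_weights_give_pure_components(self, gomp, sn_dp):
        pure_g = mixture_rvs(gomp, sn_dp, 1.0, 20_000, 9)
        pure_s = mixture_rvs(gomp, sn_dp, 0.0, 20_000, 9)
        ks_g = stats.kstest(pure_g, lambda t: 1 - gompertz_pdf_sf_hazard(t, gomp)[1])
        ks_s = stats.kstest(pure_s, lambda y: np.vectorize(lambda v: sn_cdf(v, sn_dp))(y))
        assert ks_g.pvalue > 0.001
        assert ks_s.pvalue > 0.001

    def test_mean_is_mixture_of_means(self, gomp, sn_dp):
        x = mixture_rvs(gomp, sn_dp, 0.5, 1_000_000, 4)
        want = 0.5 * gompertz_mean(gomp) + 0.5 * sn_mean_var(sn_dp)[0]
        assert x.mean() == pytest.approx(want, abs=3 * x.std() / math.sqrt(x.size))

    def test_invalid_weight_rejected(self, gomp, sn_dp):
        with pytest.raises(ValueError):
            mixture_rvs(gomp, sn_dp, 1.5, 10, 0)
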