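"""Likelihood oracles and parameter recovery for the CP-scale regressions."""

import math

import numpy as np
import pytest
from scipy import integrate

from snsurv.data import make_survival_y
from snsurv.distributions import SkewNormalCP, cp_to_dp, sn_pdf, sn_rvs
from snsurv.estimation import (
    GaussianSurvivalRegression,
    SkewNormalSurvivalRegression,
    fit_censored_gaussian,
    fit_censored_sn,
    sn_negloglik,
    standard_errors,
)


class TestNegativeLogLikelihood:
    def test_reduces_to_gaussian(self):
        rng = np.random.default_rng(0)
        y_vals = rng.normal(5.0, 2.0, 50)
        y = make_survival_y(y_vals)
        cp = SkewNormalCP(5.0, 2.0, 0.0)
        got = sn_negloglik(cp, None, None, y)
        z = (y_vals - 5.0) / 2.0
        want = np.sum(math.log(2.0) + 0.5 * math.log(2 * math.pi) + 0.5 * z**2)
        assert got == pytest.approx(want, rel=1e-12)

    def test_single_truncated_event_against_quadrature(self):
        # one death at y=80 observed from entry age 70: the contribution is
        # -log[ g(80) / S(70) ], both factors by quadrature of the density
        cp = SkewNormalCP(82.0, 11.0, -0.7)
        dp = cp_to_dp(cp)
        y = make_survival_y([80.0], event=[1.0], entry=[70.0])
        got = sn_negloglik(cp, None, None, y)
        g = sn_pdf(80.0, dp)
        S70, _ = integrate.quad(lambda v: sn_pdf(v, dp), 70.0, 200.0)
        assert got == pytest.approx(-math.log(g / S70), abs=1e-8)

    def test_all_censored_is_survival_sum(self):
        cp = SkewNormalCP(80.0, 10.0, 0.3)
        dp = cp_to_dp(cp)
        n = 7
        y = make_survival_y(np.full(n, 85.0), event=np.zeros(n))
        S85, _ = integrate.quad(lambda v: sn_pdf(v, dp), 85.0, 220.0)
        assert sn_negloglik(cp, None, None, y) == pytest.approx(-n * math.log(S85), abs=1e-7)

    def test_mixed_toy_against_quadrature(self):
        # <=10 records covering all three contribution types
        cp = SkewNormalCP(81.0, 12.0, -0.4)
        dp = cp_to_dp(cp)
        entry = np.array([-np.inf, 60.0, 70.0, -np.inf, 75.0])
        time = np.array([78.0, 84.0, 79.0, 90.0, 83.0])
        event = np.array([1.0, 1.0, 0.0, 0.0, 1.0])
        y = make_survival_y(time, event, entry)

        def S(a):
            v, _ = integrate.quad(lambda u: sn_pdf(u, dp), a, 260.0, limit=200)
            return v

        want = 0.0
        for d, t, e in zip(entry, time, event):
            want -= math.log(sn_pdf(t, dp)) if e else math.log(S(t))
            if np.isfinite(d):
                want += math.log(S(d))
        assert sn_negloglik(cp, None, None, y) == pytest.approx(want, abs=1e-6)

    def test_impossible_entry_raises(self):
        cp = SkewNormalCP(50.0, 1.0, 0.0)
        y = make_survival_y([200.0], event=[1.0], entry=[199.0])
        with pytest.raises(FloatingPointError):
            sn_negloglik(cp, None, None, y)


class TestSkewNormalFit:
    def test_recovers_study_truth_uncensored(self, sn_cp, sn_sample_10k):
        fit = fit_censored_sn(make_survival_y(sn_sample_10k))
        se = standard_errors(fit)["se"]
        assert fit.converged_
        assert abs(fit.mean_ - sn_cp.mu) < 3 * se["mu"]
        assert abs(fit.sd_ - sn_cp.s) < 3 * se["s"]
        assert abs(fit.skew_ - sn_cp.gamma1) < 3 * se["gamma1"]

    def test_recovers_covariate_effect(self, sn_cp):
        rng = np.random.default_rng(11)
        n = 4000
        x = (rng.random(n) < 0.5).astype(float)
        eps = sn_rvs(cp_to_dp(SkewNormalCP(0.0, sn_cp.s, sn_cp.gamma1)), n, rng)
        yv = 80.0 + 5.0 * x + eps
        fit = fit_censored_sn(make_survival_y(yv), X=x[:, None])
        se = standard_errors(fit)["se"]
        assert abs(fit.coef_[0] - 5.0) < 3 * se["beta0"]
        # reference-group mean is the location
        assert abs(fit.mean_ - 80.0) < 3 * se["mu"]

    def test_gaussian_truth_nests(self):
        rng = np.random.default_rng(5)
        yv = rng.normal(70.0, 8.0, 3000)
        y = make_survival_y(yv)
        sn = fit_censored_sn(y)
        ga = fit_censored_gaussian(y)
        se = standard_errors(sn)["se"]
        assert abs(sn.skew_) < 3 * se["gamma1"]
        assert abs(sn.loglik_ - ga.loglik_) < 2.0

    def test_zero_events_refused(self):
        y = make_survival_y([80.0, 81.0], event=[0.0, 0.0])
        with pytest.raises(ValueError, match="events"):
            fit_censored_sn(y)
        fit = SkewNormalSurvivalRegression(allow_all_censored=True).fit(None, y)
        assert fit.n_events_ == 0

    def test_location_equivariance(self, sn_sample_10k):
        y1 = make_survival_y(sn_sample_10k[:2000])
        y2 = make_survival_y(sn_sample_10k[:2000] + 7.0)
        f1 = fit_censored_sn(y1)
        f2 = fit_censored_sn(y2)
        assert f2.mean_ - f1.mean_ == pytest.approx(7.0, abs=1e-3)
        assert f2.sd_ == pytest.approx(f1.sd_, abs=1e-3)
        assert f2.skew_ == pytest.approx(f1.skew_, abs=1e-3)

    def test_likelihood_improves_on_moment_start(self, sn_sample_10k):
        fit = fit_censored_sn(make_survival_y(sn_sample_10k[:1000]))
        assert fit.loglik_ >= fit.loglik_start_ - 1e-9

    def test_truncation_consistency(self, sn_sample_10k):
        # entry ages far below every exit age: S(D) ~ 1, fit unchanged
        yv = sn_sample_10k[:1500]
        plain = fit_censored_sn(make_survival_y(yv))
        trunc = fit_censored_sn(make_survival_y(yv, entry=np.full(yv.size, -300.0)))
        assert trunc.loglik_ == pytest.approx(plain.loglik_, abs=1e-6)
        assert trunc.mean_ == pytest.approx(plain.mean_, abs=1e-6)

    def test_censored_truncated_recovery(self, sn_cp):
        # census-cohort design: ~88% censored, delayed entry; location recovered
        from snsurv.lifetable import CohortConfig, generate_cohort

        _, y, info = generate_cohort(CohortConfig(n_subjects=20_000, seed=21))
        assert 0.80 < info["censoring_proportion"] < 0.95
        fit = fit_censored_sn(y)
        se = standard_errors(fit)["se"]
        assert abs(fit.mean_ - sn_cp.mu) < 3 * se["mu"]


class TestGaussianFit:
    def test_uncensored_matches_ols(self):
        rng = np.random.default_rng(2)
        n = 800
        x = rng.random(n)
        yv = 60.0 + 3.0 * x + rng.normal(0, 4.0, n)
        fit = fit_censored_gaussian(make_survival_y(yv), X=x[:, None])
        Xd = np.column_stack([np.ones(n), x])
        beta_ols = np.linalg.lstsq(Xd, yv, rcond=None)[0]
        resid = yv - Xd @ beta_ols
        assert fit.mean_ == pytest.approx(beta_ols[0], abs=1e-4)
        assert fit.coef_[0] == pytest.approx(beta_ols[1], abs=1e-3)
        # MLE variance uses denominator n
        assert fit.sd_ == pytest.approx(math.sqrt(np.mean(resid**2)), abs=1e-4)

    def test_tobit_toy_against_grid_search(self):
        # 10 records, right-censored at 6: dense (mu, s) grid as oracle
        time = np.array([2.1, 3.4, 4.0, 5.2, 6.0, 6.0, 6.0, 1.8, 4.9, 6.0])
        event = np.array([1, 1, 1, 1, 0, 0, 0, 1, 1, 0], dtype=float)
        y = make_survival_y(time, event)
        fit = fit_censored_gaussian(y)

        from scipy.stats import norm

        def nll(mu, s):
            obs = event == 1
            out = -np.sum(norm.logpdf(time[obs], mu, s))
            out -= np.sum(norm.logsf(time[~obs], mu, s))
            return out

        mus = np.linspace(2.0, 8.0, 241)
        ss = np.linspace(0.5, 5.0, 181)
        grid = np.array([[nll(m, s) for s in ss] for m in mus])
        i, j = np.unravel_index(np.argmin(grid), grid.shape)
        assert fit.mean_ == pytest.approx(mus[i], abs=0.05)
        assert fit.sd_ == pytest.approx(ss[j], abs=0.05)
        assert -fit.loglik_ <= grid.min() + 1e-6

    def test_reduction_from_skew_normal(self):
        # gamma1 -> 0 censored SN loglik equals the censored Gaussian one
        rng = np.random.default_rng(8)
        time = rng.normal(75, 9, 40)
        event = (rng.random(40) < 0.6).astype(float)
        time[event == 0] -= 5.0
        y = make_survival_y(time, event)
        ga = fit_censored_gaussian(y)
        cp = SkewNormalCP(ga.mean_, ga.sd_, 0.0)
        assert sn_negloglik(cp, None, None, y) == pytest.approx(-ga.loglik_, abs=1e-6)


class TestStandardErrors:
    def test_interval_symmetry(self, sn_sample_10k):
        fit = fit_censored_sn(make_survival_y(sn_sample_10k[:2000]))
        t = standard_errors(fit)
        assert np.allclose(t["ci_high"] - t["estimate"], t["estimate"] - t["ci_low"])

    def test_degenerate_covariance_rejected(self, sn_sample_10k):
        fit = fit_censored_sn(make_survival_y(sn_sample_10k[:500]))
        fit.covariance_ = np.zeros_like(fit.covariance_)
        with pytest.raises(ValueError, match="degenerate"):
            standard_errors(fit)
        fit.covariance_ = None
        with pytest.raises(ValueError, match="covariance"):
            standard_errors(fit)

    def test_se_calibration_against_replicates(self, sn_cp):
        # empirical SD of the location over replicates vs mean reported SE
        dp = cp_to_dp(sn_cp)
        rng = np.random.default_rng(99)
        mus, ses = [], []
        for _ in range(200):
            fit = fit_censored_sn(make_survival_y(sn_rvs(dp, 500, rng)))
            if fit.covariance_ is not None:
                mus.append(fit.mean_)
                ses.append(math.sqrt(fit.covariance_[0, 0]))
        emp = np.std(mus, ddof=1)
        assert np.mean(ses) == pytest.approx(emp, rel=0.2)
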