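"""Parametric proportional-hazards and accelerated-failure-time regressions.

Comparators for the skew-normal regression, all fitted by the same censored,
left-truncated likelihood construction: an event contributes log f(t|X), a
censored subject log S(c|X), and every subject with delayed entry D > 0 is
conditioned on survival to entry by subtracting log S(D|X).

* PH (Weibull or Gompertz baseline): lambda(t|X) = lambda(t) exp(X'beta);
  coefficients are log hazard ratios.
* AFT (Weibull or log-normal): log T = m + X'beta + sigma*eps; coefficients
  are log time ratios.

The Weibull PH and Weibull AFT models are the same distribution family and
attain identical maximized likelihoods, with beta_AFT = -beta_PH / gamma.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import optimize, special
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .data import check_survival_y
from .distributions import GompertzParams, LogNormalParams, WeibullParams
from .estimation import _numeric_hessian, _safe_inverse

__all__ = ["ParametricPHRegression", "ParametricAFTRegression", "fit_ph", "fit_aft"]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _prep(X, y, positive_times: bool):
    entry, time, event = check_survival_y(y)
    if positive_times and np.any(time <= 0):
        raise ValueError("this model requires strictly positive exit times")
    if X is not None:
        X = check_array(X, ensure_min_features=0)
        if X.shape[1] == 0:
            X = None
        elif X.shape[0] != time.shape[0]:
            raise ValueError("X and y have different numbers of rows")
    d = np.where(np.isfinite(entry), np.maximum(entry, 0.0), 0.0)
    return X, d, time, event


class _BaseParametricSurvival(BaseEstimator):
    def __init__(self, distribution, max_iter=500, gtol=1e-6):
        self.distribution = distribution
        self.max_iter = max_iter
        self.gtol = gtol

    def fit(self, X, y):
        if self.distribution not in self._distributions:
            raise ValueError(
                f"distribution must be one of {self._distributions}, "
                f"got {self.distribution!r}"
            )
        X, d, time, event = _prep(X, y, positive_times=True)
        self.n_features_in_ = 0 if X is None else X.shape[1]
        self.n_events_ = int(event.sum())
        self.n_censored_ = int(time.shape[0] - self.n_events_)
        if self.n_events_ == 0:
            raise ValueError("no observed events")
        k = self.n_features_in_

        def nll(theta):
            val = -self._loglik(theta, X, d, time, event)
            return val if np.isfinite(val) else 1e12

        theta0 = self._starting_values(d, time, event, k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.minimize(
                nll, theta0, method="L-BFGS-B", bounds=self._bounds(k),
                options={"maxiter": self.max_iter, "gtol": self.gtol, "ftol": 1e-12},
            )
        self.theta_opt_ = res.x.copy()  # optimized-scale copy used by _logsf/_logpdf
        self.coef_ = res.x[2:].copy()
        self.loglik_ = -float(res.fun)
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        self._set_params_from_theta(res.x)
        self.param_names_ = self._theta_names(k)
        # estimates and covariance are reported on the optimized scale
        # (positivity-constrained parameters on log scale), so MVN parameter
        # draws respect the constraints by construction
        self.theta_hat_ = res.x.copy()
        self.covariance_ = None
        if self.converged_:
            self.covariance_ = _safe_inverse(_numeric_hessian(nll, res.x))
        return self

    # helpers shared by subclasses -----------------------------------------

    def _xb(self, X_theta, X):
        if X is None:
            return 0.0
        return X @ X_theta

    def linear_predictor(self, X=None):
        check_is_fitted(self, "theta_hat_")
        if X is None or self.n_features_in_ == 0:
            return np.zeros(1)
        return check_array(X) @ self.coef_

    def survival_function(self, t, X=None):
        """S(t | X); with an (n, k) X and array ``t`` returns (n, len(t))."""
        xb = self.linear_predictor(X)
        t = np.asarray(t, dtype=float)
        if xb.size > 1 and t.ndim:
            return np.exp(self._logsf(t[None, :], xb[:, None]))
        x0 = xb if xb.size > 1 else float(xb[0])
        out = np.exp(self._logsf(t, x0))
        return float(out) if np.ndim(out) == 0 else out

    def log_density(self, t, X=None):
        xb = self.linear_predictor(X)
        t = np.asarray(t, dtype=float)
        x0 = xb if xb.size > 1 and t.ndim == 0 else float(xb[0]) if xb.size == 1 else xb
        return self._logpdf(t, x0)

    def log_hazard(self, t, X=None):
        xb = self.linear_predictor(X)
        t = np.asarray(t, dtype=float)
        x0 = float(xb[0]) if xb.size == 1 else xb
        return self._logpdf(t, x0) - self._logsf(t, x0)

    def predict(self, X=None):
        """Expected survival time E(T | X) (closed form)."""
        check_is_fitted(self, "theta_hat_")
        xb = self.linear_predictor(X)
        return self._mean_from_theta(self.theta_hat_[None, :2], xb)

    def mean_survival_time(self, X=None):
        return self.predict(X)

    def _theta_valid(self, draws):
        # the optimized scale keeps constrained parameters unconstrained
        return np.ones(draws.shape[0], dtype=bool)


class ParametricPHRegression(_BaseParametricSurvival):
    """Proportional-hazards regression with Weibull or Gompertz baseline.

    Attributes after fit: ``params_`` (baseline :class:`WeibullParams` or
    :class:`GompertzParams`), ``coef_`` (log hazard ratios), ``loglik_``,
    ``theta_hat_``/``covariance_`` on the optimized scale (log alpha,
    log gamma, beta), ``boundary_`` flags a Gompertz shape pinned at its
    positivity bound.
    """

    _distributions = ("weibull", "gompertz")

    def _theta_names(self, k):
        return ["log_alpha", "log_gamma"] + [f"beta{i}" for i in range(k)]

    def _bounds(self, k):
        return [(-40.0, 10.0), (-10.0, 4.0)] + [(None, None)] * k

    def _starting_values(self, d, time, event, k):
        rate = max(event.sum() / np.sum(time - d), 1e-10)
        if self.distribution == "weibull":
            # exponential start: gamma = 1, alpha = 1/rate
            return np.asarray([math.log(1.0 / rate), 0.0] + [0.0] * k)
        # Gompertz: modest senescence slope, hazard matching at mean age
        g0 = 0.05
        a0 = rate * math.exp(-g0 * float(np.mean(time)))
        return np.asarray([math.log(max(a0, 1e-12)), math.log(g0)] + [0.0] * k)

    def _log_hazard_cumhaz(self, t, la, lg):
        a, g = np.exp(la), np.exp(lg)
        if self.distribution == "gompertz":
            logh = la + g * t
            H = (a / g) * np.expm1(g * t)
        else:
            logh = lg - la + (g - 1.0) * (np.log(t) - la)
            H = np.exp(g * (np.log(t) - la))
        return logh, H

    def _loglik(self, theta, X, d, time, event):
        la, lg = theta[0], theta[1]
        xb = self._xb(theta[2:], X)
        ex = np.exp(xb)
        logh_t, H_t = self._log_hazard_cumhaz(time, la, lg)
        H_d = np.where(d > 0, self._log_hazard_cumhaz(np.maximum(d, 1e-300), la, lg)[1], 0.0)
        ev = event == 1
        ll = float(np.sum((logh_t[ev] + (xb[ev] if np.ndim(xb) else xb))))
        ll -= float(np.sum(ex * (H_t - H_d)))
        return ll

    def _set_params_from_theta(self, theta):
        a, g = math.exp(theta[0]), math.exp(theta[1])
        if self.distribution == "gompertz":
            self.params_ = GompertzParams(alpha=a, gamma=g)
            self.boundary_ = theta[1] <= -10.0 + 1e-6
        else:
            self.params_ = WeibullParams(alpha=a, gamma=g)
            self.boundary_ = False

    def _logsf(self, t, xb):
        la, lg = self.theta_opt_[0], self.theta_opt_[1]
        _, H = self._log_hazard_cumhaz(np.maximum(t, 1e-300), la, lg)
        return -np.exp(xb) * H

    def _logpdf(self, t, xb):
        la, lg = self.theta_opt_[0], self.theta_opt_[1]
        logh, H = self._log_hazard_cumhaz(np.maximum(t, 1e-300), la, lg)
        return logh + xb - np.exp(xb) * H

    def hazard_ratios(self):
        """exp(beta): multiplicative effect on the hazard per covariate unit."""
        check_is_fitted(self, "theta_hat_")
        return np.exp(self.coef_)

    def _mean_from_theta(self, draws, xb):
        """E(T | X) per parameter draw (log alpha, log gamma in draws)."""
        a, g = np.exp(draws[:, 0]), np.exp(draws[:, 1])
        xb = np.asarray(xb, dtype=float)
        if self.distribution == "gompertz":
            r = a * np.exp(xb) / g
            return np.exp(r) * special.exp1(r) / g
        return a * np.exp(-xb / g) * special.gamma(1.0 + 1.0 / g)


class ParametricAFTRegression(_BaseParametricSurvival):
    """Accelerated-failure-time regression: log T = m + X'beta + sigma*eps.

    ``distribution`` selects the error law: "lognormal" (eps standard
    normal) or "weibull" (eps standard minimum Gumbel).  Coefficients are
    log time ratios.  Attributes after fit: ``intercept_`` (m), ``scale_``
    (sigma), ``params_`` (:class:`WeibullParams` with alpha = exp(m),
    gamma = 1/sigma, or :class:`LogNormalParams`), ``theta_hat_`` and
    ``covariance_`` on the optimized scale (m, log sigma, beta).
    """

    _distributions = ("weibull", "lognormal")

    def _theta_names(self, k):
        return ["intercept", "log_sigma"] + [f"beta{i}" for i in range(k)]

    def _bounds(self, k):
        return [(None, None), (-10.0, 5.0)] + [(None, None)] * k

    def _starting_values(self, d, time, event, k):
        obs = np.log(time[event == 1]) if event.sum() >= 5 else np.log(time)
        return np.asarray(
            [float(np.mean(obs)), math.log(max(float(np.std(obs)), 1e-3))] + [0.0] * k
        )

    @staticmethod
    def _eps_logpdf_logsf(u, dist):
        if dist == "lognormal":
            return (-0.5 * u * u - _LOG_SQRT_2PI), special.log_ndtr(-u)
        # minimum-Gumbel errors give Weibull times
        eu = np.exp(np.minimum(u, 500.0))
        return (u - eu), -eu

    def _loglik(self, theta, X, d, time, event):
        m, ls = theta[0], theta[1]
        sigma = math.exp(ls)
        xb = self._xb(theta[2:], X)
        u = (np.log(time) - m - xb) / sigma
        lp, lsf = self._eps_logpdf_logsf(u, self.distribution)
        ev = event == 1
        ll = float(np.sum(lp[ev] - np.log(time[ev]))) - ls * int(ev.sum())
        ll += float(np.sum(lsf[~ev]))
        td = d > 0
        if np.any(td):
            ud = (np.log(d[td]) - m - (xb[td] if np.ndim(xb) else xb)) / sigma
            ll -= float(np.sum(self._eps_logpdf_logsf(ud, self.distribution)[1]))
        return ll

    def _set_params_from_theta(self, theta):
        self.intercept_ = float(theta[0])
        self.scale_ = float(math.exp(theta[1]))
        if self.distribution == "weibull":
            self.params_ = WeibullParams(
                alpha=math.exp(self.intercept_), gamma=1.0 / self.scale_
            )
        else:
            self.params_ = LogNormalParams(mu=self.intercept_, alpha=self.scale_)
        self.boundary_ = False

    def _logsf(self, t, xb):
        m, sigma = self.intercept_, self.scale_
        u = (np.log(np.maximum(t, 1e-300)) - m - xb) / sigma
        return self._eps_logpdf_logsf(u, self.distribution)[1]

    def _logpdf(self, t, xb):
        m, sigma = self.intercept_, self.scale_
        t = np.maximum(t, 1e-300)
        u = (np.log(t) - m - xb) / sigma
        return self._eps_logpdf_logsf(u, self.distribution)[0] - math.log(sigma) - np.log(t)

    def time_ratios(self):
        """exp(beta): multiplicative effect on survival time per covariate unit."""
        check_is_fitted(self, "theta_hat_")
        return np.exp(self.coef_)

    def _mean_from_theta(self, draws, xb):
        m, sigma = draws[:, 0], np.exp(draws[:, 1])
        xb = np.asarray(xb, dtype=float)
        if self.distribution == "lognormal":
            return np.exp(m + xb + 0.5 * sigma**2)
        return np.exp(m + xb) * special.gamma(1.0 + sigma)


def fit_ph(y, X=None, distribution="gompertz", **kwargs) -> ParametricPHRegression:
    """Functional wrapper: censored, left-truncated PH fit."""
    return ParametricPHRegression(distribution=distribution, **kwargs).fit(X, y)


def fit_aft(y, X=None, distribution="weibull", **kwargs) -> ParametricAFTRegression:
    """Functional wrapper: censored, left-truncated AFT fit."""
    return ParametricAFTRegression(distribution=distribution, **kwargs).fit(X, y)
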