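"""Censored, left-truncated skew-normal and Gaussian regression by MLE.

Model:  Y_i = mu + X_i' beta + eps_i with eps_i ~ SN(0-mean, s^2, gamma1) in
the centered parametrization (CP).  Each subject contributes

    delta_i * log g(y_i)  +  (1 - delta_i) * log S(c_i)  -  log S(D_i)

where g and S are the skew-normal density and survival function with
per-subject location mu + X_i' beta, delta_i the death indicator, c_i the
censoring age and D_i the delayed-entry (left-truncation) age; subjects
observed from the time origin (D_i = -inf) contribute no truncation term.

Optimization is on the CP scale, which removes the profile-likelihood
singularity of the direct parametrization at psi = 0 and makes the fitted
location parameter equal the distribution mean (so its Wald interval is a
confidence interval for the mean life expectancy directly).  The Gaussian
regression is the gamma1 = 0 special case, fitted by the same machinery.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import optimize, special
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .data import check_survival_y
from .distributions import (
    GAMMA1_MARGIN,
    SkewNormalCP,
    SkewNormalDP,
    _sn_sf_quad,
    cp_to_dp,
    gamma1_max,
)

__all__ = [
    "SkewNormalSurvivalRegression",
    "GaussianSurvivalRegression",
    "sn_negloglik",
    "fit_censored_sn",
    "fit_censored_gaussian",
    "standard_errors",
]

_LOG_2 = math.log(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_SF_FLOOR = 1e-300


def _cp_aux(s: float, gamma1: float):
    """(sigma, psi, mz) of the DP triple matching CP (0, s, gamma1).

    mz is the mean of the standardized SN variate, so xi = loc - sigma * mz
    converts a CP location into a DP location.
    """
    t = math.copysign(abs(2.0 * gamma1 / (4.0 - math.pi)) ** (1.0 / 3.0), gamma1)
    mz = t / math.hypot(1.0, t)
    delta = mz / math.sqrt(2.0 / math.pi)
    psi = delta / math.sqrt(max(1.0 - delta * delta, 1e-12))
    sigma = s / math.sqrt(1.0 - mz * mz)
    return sigma, psi, mz


def _logpdf_z(z, psi):
    """Log of the standardized SN density 2 phi(z) Phi(psi z)."""
    return _LOG_2 - 0.5 * z * z - _LOG_SQRT_2PI + special.log_ndtr(psi * z)


def _sf_z(z, psi):
    """Upper-tail probability of the standardized SN, tail-refined."""
    out = special.ndtr(-z) + 2.0 * special.owens_t(z, psi)
    if psi < 0:
        tiny = (out < 1e-10) & (z > 0)
        if np.any(tiny):
            for i in np.nonzero(tiny)[0]:
                out[i] = _sn_sf_quad(float(z[i]), psi)
    return np.clip(out, 0.0, 1.0)


class _NegLogLik:
    """Negative log-likelihood on the CP scale; tracks floored tail terms."""

    def __init__(self, X, entry, time, event, fix_skew: bool, gamma1_bound: float):
        self.X = X
        self.entry = entry
        self.time = time
        self.event = event == 1
        self.cens = ~self.event
        self.trunc = np.isfinite(entry)
        self.fix_skew = fix_skew
        self.gamma1_bound = gamma1_bound
        self.k = 0 if X is None else X.shape[1]
        self.n_floored = 0

    def unpack(self, theta):
        mu, s = theta[0], theta[1]
        if self.fix_skew:
            gamma1, beta = 0.0, theta[2:]
        else:
            gamma1, beta = theta[2], theta[3:]
        return mu, s, gamma1, beta

    def __call__(self, theta) -> float:
        mu, s, gamma1, beta = self.unpack(theta)
        if not (s > 0) or abs(gamma1) > self.gamma1_bound:
            return 1e12
        sigma, psi, mz = _cp_aux(s, gamma1)
        loc = mu if self.k == 0 else mu + self.X @ beta
        xi = loc - sigma * mz
        z = (self.time - xi) / sigma
        ll = 0.0
        self.n_floored = 0
        if self.event.any():
            ll += float(np.sum(_logpdf_z(z[self.event], psi))) - math.log(sigma) * int(
                self.event.sum()
            )
        if self.cens.any():
            sf = _sf_z(np.atleast_1d(z[self.cens]), psi)
            self.n_floored += int(np.sum(sf <= _SF_FLOOR))
            ll += float(np.sum(np.log(np.maximum(sf, _SF_FLOOR))))
        if self.trunc.any():
            zd = (self.entry[self.trunc] - (xi[self.trunc] if np.ndim(xi) else xi)) / sigma
            sfd = _sf_z(np.atleast_1d(zd), psi)
            self.n_floored += int(np.sum(sfd <= _SF_FLOOR))
            ll -= float(np.sum(np.log(np.maximum(sfd, _SF_FLOOR))))
        if not np.isfinite(ll):
            return 1e12
        return -ll


def sn_negloglik(cp: SkewNormalCP, beta, X, y) -> float:
    """Censored, left-truncated skew-normal negative log-likelihood.

    Direct evaluation contract: raises if any subject's entry-survival
    S(D_i) underflows to zero (the parameters are incompatible with the
    subject having survived to entry).
    """
    entry, time, event = check_survival_y(y)
    beta = np.asarray([] if beta is None else beta, dtype=float)
    Xa = None if beta.size == 0 else check_array(X)
    nll = _NegLogLik(Xa, entry, time, event, False, gamma1_max() - GAMMA1_MARGIN)
    theta = np.concatenate([[cp.mu, cp.s, cp.gamma1], beta])
    val = nll(theta)
    if nll.n_floored:
        raise FloatingPointError(
            f"{nll.n_floored} likelihood term(s) underflowed: a subject cannot "
            "have survived to entry/censoring under these parameters"
        )
    return val


def _numeric_hessian(f, x, rel_step=1e-4):
    """Central-difference Hessian of scalar ``f`` at ``x``."""
    x = np.asarray(x, dtype=float)
    p = x.size
    # steps proportional to parameter magnitude (natural parameters can be
    # orders of magnitude apart, e.g. a Gompertz alpha ~ 1e-6)
    h = rel_step * np.where(np.abs(x) > 1e-12, np.abs(x), 1.0)
    H = np.empty((p, p))
    f0 = f(x)

    def fs(steps):
        xx = x.copy()
        for j, s in steps:
            xx[j] += s
        return f(xx)

    for j in range(p):
        H[j, j] = (fs([(j, h[j])]) - 2.0 * f0 + fs([(j, -h[j])])) / h[j] ** 2
        for k in range(j + 1, p):
            v = (
                fs([(j, h[j]), (k, h[k])])
                - fs([(j, h[j]), (k, -h[k])])
                - fs([(j, -h[j]), (k, h[k])])
                + fs([(j, -h[j]), (k, -h[k])])
            ) / (4.0 * h[j] * h[k])
            H[j, k] = H[k, j] = v
    return H


def _safe_inverse(H):
    """Inverse of a Hessian if it is positive definite, else None."""
    try:
        L = np.linalg.cholesky(H)
        inv = np.linalg.inv(H)
        return 0.5 * (inv + inv.T)
    except np.linalg.LinAlgError:
        return None


class _BaseCenteredRegression(BaseEstimator):
    """Shared MLE machinery for the skew-normal and Gaussian regressions."""

    _fix_skew: bool

    def __init__(self, max_iter=500, gtol=1e-6, gamma1_margin=GAMMA1_MARGIN,
                 allow_all_censored=False, init=None):
        self.max_iter = max_iter
        self.gtol = gtol
        self.gamma1_margin = gamma1_margin
        self.allow_all_censored = allow_all_censored
        self.init = init

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y):
        """Fit by maximum likelihood.

        ``X`` is an (n, k) covariate matrix or None; ``y`` is the survival
        target [entry, time, event] (see :mod:`snsurv.data`).
        """
        entry, time, event = check_survival_y(y)
        if X is not None:
            X = check_array(X, ensure_min_features=0)
            if X.shape[1] == 0:
                X = None
            elif X.shape[0] != time.shape[0]:
                raise ValueError("X and y have different numbers of rows")
        self.n_features_in_ = 0 if X is None else X.shape[1]
        k = self.n_features_in_
        self.n_events_ = int(event.sum())
        self.n_censored_ = int(time.shape[0] - self.n_events_)
        if self.n_events_ == 0 and not self.allow_all_censored:
            raise ValueError(
                "no observed events: the likelihood may be unbounded "
                "(pass allow_all_censored=True to override)"
            )

        bound = gamma1_max() - self.gamma1_margin
        nll = _NegLogLik(X, entry, time, event, self._fix_skew, bound)

        theta0 = self._starting_values(time, event, k, bound)
        self.loglik_start_ = -nll(theta0)

        p = theta0.size
        # optimize with s on log scale for positivity
        def obj(u):
            th = u.copy()
            th[1] = math.exp(u[1])
            return nll(th)

        u0 = theta0.copy()
        u0[1] = math.log(theta0[1])
        bounds = [(None, None), (-30.0, 30.0)]
        if not self._fix_skew:
            bounds.append((-bound, bound))
        bounds += [(None, None)] * k
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.minimize(
                obj, u0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": self.max_iter, "gtol": self.gtol, "ftol": 1e-12},
            )
        theta = res.x.copy()
        theta[1] = math.exp(res.x[1])
        self.theta_hat_ = theta.copy()
        mu, s, gamma1, beta = nll.unpack(theta)

        self.mean_ = float(mu)
        self.sd_ = float(s)
        self.skew_ = float(gamma1)
        self.coef_ = np.asarray(beta, dtype=float)
        self.loglik_ = -float(res.fun)
        self.n_iter_ = int(res.nit)
        self.converged_ = bool(res.success)
        self.n_floored_ = int(nll.n_floored)
        g_cp = float(np.clip(gamma1, -(gamma1_max() - GAMMA1_MARGIN),
                             gamma1_max() - GAMMA1_MARGIN))
        self.cp_ = SkewNormalCP(self.mean_, self.sd_, g_cp)
        self.dp_ = (SkewNormalDP(self.mean_, self.sd_, 0.0) if self._fix_skew
                    else cp_to_dp(self.cp_))

        self.param_names_ = (
            ["mu", "s"] + ([] if self._fix_skew else ["gamma1"])
            + [f"beta{i}" for i in range(k)]
        )
        self.covariance_ = None
        if self.converged_:
            H = _numeric_hessian(nll, theta)
            self.covariance_ = _safe_inverse(H)
            if self.covariance_ is None:
                warnings.warn(
                    "Hessian not positive definite at the optimum; "
                    "covariance withheld", RuntimeWarning,
                )
        return self

    def _starting_values(self, time, event, k, bound):
        if self.init is not None:
            return np.asarray(self.init, dtype=float)
        obs = time[event == 1] if event.sum() >= 5 else time
        mu0 = float(np.mean(obs))
        s0 = max(float(np.std(obs)), 1e-3)
        theta = [mu0, s0]
        if not self._fix_skew:
            m3 = float(np.mean((obs - mu0) ** 3))
            g0 = float(np.clip(m3 / s0**3, -0.9 * bound, 0.9 * bound))
            theta.append(g0)
        return np.asarray(theta + [0.0] * k, dtype=float)

    # -- fitted-model surfaces --------------------------------------------

    def _dp_at(self, X=None):
        """Per-row DP location xi plus common (sigma, psi)."""
        check_is_fitted(self, "mean_")
        sigma, psi, mz = _cp_aux(self.sd_, self.skew_)
        if X is None or self.n_features_in_ == 0:
            loc = np.asarray([self.mean_])
        else:
            X = check_array(X)
            loc = self.mean_ + X @ self.coef_
        return loc - sigma * mz, sigma, psi

    def predict(self, X=None):
        """Expected survival age E(Y | X) = mu + X' beta (CP location is the mean)."""
        check_is_fitted(self, "mean_")
        if X is None or self.n_features_in_ == 0:
            return np.asarray([self.mean_])
        X = check_array(X)
        return self.mean_ + X @ self.coef_

    def _z_grid(self, t, X):
        xi, sigma, psi = self._dp_at(X)
        t = np.asarray(t, dtype=float)
        if xi.size == 1:
            z = (t - xi[0]) / sigma
        elif t.ndim == 0:
            z = (float(t) - xi) / sigma
        else:
            z = (t[None, :] - xi[:, None]) / sigma
        return z, sigma, psi

    def survival_function(self, t, X=None):
        """S(t | X).  With an (n, k) X and an array ``t``, returns (n, len(t))."""
        z, _, psi = self._z_grid(t, X)
        shape = np.shape(z)
        out = _sf_z(np.atleast_1d(np.asarray(z, float)).ravel(), psi)
        return float(out[0]) if shape == () else out.reshape(shape)

    def log_density(self, t, X=None):
        z, sigma, psi = self._z_grid(t, X)
        return _logpdf_z(z, psi) - math.log(sigma)

    def mean_survival_time(self, X=None):
        """Alias of :meth:`predict`; the CP location is the distribution mean."""
        return self.predict(X)

    def conf_int(self, alpha=0.05):
        """Wald confidence intervals on the CP scale (DataFrame)."""
        return standard_errors(self, alpha=alpha)

    # hooks for the sampling-based life-expectancy intervals ---------------

    def _theta_valid(self, draws):
        ok = draws[:, 1] > 0
        if not self._fix_skew:
            ok &= np.abs(draws[:, 2]) < gamma1_max() - self.gamma1_margin
        return ok

    def _mean_from_theta(self, draws, xb):
        return draws[:, 0] + np.asarray(xb, dtype=float)


class SkewNormalSurvivalRegression(_BaseCenteredRegression):
    """Censored, left-truncated skew-normal regression (CP scale MLE).

    Parameters
    ----------
    max_iter : int
        L-BFGS-B iteration cap.
    gtol : float
        Projected-gradient tolerance for convergence.
    gamma1_margin : float
        Interior margin kept from the +-0.99527 skewness boundary.
    allow_all_censored : bool
        Permit fitting with zero observed events (normally refused).
    init : array-like or None
        Optional starting values [mu, s, gamma1, beta...]; defaults to
        censoring-unadjusted moments with clipped moment skewness.

    Attributes
    ----------
    mean_, sd_, skew_ : CP estimates (mu, s, gamma1); ``mean_`` is the
        fitted mean life expectancy at X = 0.
    coef_ : regression coefficients (years per covariate unit).
    dp_ : the equivalent direct parametrization (xi, sigma, psi).
    covariance_ : inverse numerical Hessian on the CP scale,
        order ``param_names_``.
    loglik_, converged_, n_events_, n_censored_, n_floored_.
    """

    _fix_skew = False

    @property
    def model_tag(self):
        return "skew_normal"


class GaussianSurvivalRegression(_BaseCenteredRegression):
    """Censored, left-truncated Gaussian regression (skewness fixed at zero).

    Identical contract to :class:`SkewNormalSurvivalRegression` with
    gamma1 = 0; this is the Tobit-type censored normal regression with
    delayed entry.
    """

    _fix_skew = True

    @property
    def model_tag(self):
        return "gaussian"


def standard_errors(fit, alpha=0.05):
    """Per-parameter SEs and Wald intervals on the optimized (CP) scale.

    Returns a DataFrame indexed by ``param_names_`` with columns
    estimate / se / ci_low / ci_high.
    """
    import pandas as pd
    from scipy.stats import norm

    check_is_fitted(fit, "mean_")
    cov = getattr(fit, "covariance_", None)
    if cov is None:
        raise ValueError("fit has no covariance; re-fit to convergence")
    if not np.any(cov):
        raise ValueError("degenerate (all-zero) covariance")
    est = np.concatenate(
        [[fit.mean_, fit.sd_], [] if fit._fix_skew else [fit.skew_], fit.coef_]
    )
    se = np.sqrt(np.diag(cov))
    zq = norm.ppf(1.0 - alpha / 2.0)
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_low": est - zq * se,
            "ci_high": est + zq * se,
        },
        index=fit.param_names_,
    )


def fit_censored_sn(y, X=None, **kwargs) -> SkewNormalSurvivalRegression:
    """Functional wrapper: fit the censored skew-normal regression."""
    return SkewNormalSurvivalRegression(**kwargs).fit(X, y)


def fit_censored_gaussian(y, X=None, **kwargs) -> GaussianSurvivalRegression:
    """Functional wrapper: fit the censored Gaussian regression."""
    return GaussianSurvivalRegression(**kwargs).fit(X, y)
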