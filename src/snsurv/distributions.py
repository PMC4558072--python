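"""Skew-normal, Gompertz, Weibull and log-normal laws.

The skew-normal distribution SN(xi, sigma^2, psi) has density

    g(y) = (2/sigma) * phi(z) * Phi(psi * z),   z = (y - xi)/sigma,

with location ``xi``, scale ``sigma > 0`` and shape ``psi`` (the *direct*
parametrization, DP).  The *centered* parametrization (CP) uses the mean
``mu``, standard deviation ``s`` and the skewness index ``gamma1``; it is the
parametrization of choice for maximum likelihood because the DP profile
likelihood is singular at ``psi = 0``.  Conversion between the two is exact
and closed-form (:func:`dp_to_cp`, :func:`cp_to_dp`).

The Gompertz and Weibull laws are given in the hazard/survival form standard
in demography; the Gompertz mean uses the exponential-integral closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

__all__ = [
    "SkewNormalDP",
    "SkewNormalCP",
    "GompertzParams",
    "WeibullParams",
    "LogNormalParams",
    "gamma1_max",
    "sn_pdf",
    "sn_logpdf",
    "sn_cdf",
    "sn_sf",
    "sn_logsf",
    "sn_mean_var",
    "sn_rvs",
    "dp_to_cp",
    "cp_to_dp",
    "gompertz_pdf_sf_hazard",
    "gompertz_mean",
    "gompertz_rvs",
    "weibull_pdf_sf_hazard",
    "weibull_mean",
    "weibull_rvs",
    "mixture_rvs",
]

_SQRT_2_PI = math.sqrt(2.0 / math.pi)
_LOG_2 = math.log(2.0)


def gamma1_max() -> float:
    """Supremum of |gamma1| for the skew-normal family (psi -> +/- inf limit).

    As psi -> inf the skewness index tends to
    ((4 - pi)/2) * (2/(pi - 2))^(3/2) ~= 0.99527; the CP is only defined
    strictly inside this bound.
    """
    return 0.5 * (4.0 - math.pi) * (2.0 / (math.pi - 2.0)) ** 1.5


#: Margin kept away from the gamma1 boundary in all CP inputs; cp_to_dp
#: diverges at the boundary itself.
GAMMA1_MARGIN = 1e-4


@dataclass(frozen=True)
class SkewNormalDP:
    """Direct parametrization (location xi, scale sigma, shape psi)."""

    xi: float
    sigma: float
    psi: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ValueError(f"sigma must be positive and finite, got {self.sigma}")
        if not (np.isfinite(self.xi) and np.isfinite(self.psi)):
            raise ValueError("xi and psi must be finite")


@dataclass(frozen=True)
class SkewNormalCP:
    """Centered parametrization (mean mu, standard deviation s, skewness gamma1)."""

    mu: float
    s: float
    gamma1: float

    def __post_init__(self) -> None:
        if not (self.s > 0 and np.isfinite(self.s)):
            raise ValueError(f"s must be positive and finite, got {self.s}")
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if abs(self.gamma1) >= gamma1_max():
            raise ValueError(
                f"|gamma1| = {abs(self.gamma1)} is outside the skew-normal "
                f"range (+-{gamma1_max():.6f})"
            )


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz law: hazard alpha * exp(gamma * t), alpha > 0, gamma > 0."""

    alpha: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.gamma > 0):
            raise ValueError("Gompertz requires alpha > 0 and gamma > 0")


@dataclass(frozen=True)
class WeibullParams:
    """Weibull law: hazard (gamma/alpha) (t/alpha)^(gamma-1), alpha > 0, gamma >= 0."""

    alpha: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.gamma >= 0):
            raise ValueError("Weibull requires alpha > 0 and gamma >= 0")


@dataclass(frozen=True)
class LogNormalParams:
    """Log-normal law: log T ~ N(mu, alpha^2)."""

    mu: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("log-normal requires alpha > 0")


# ---------------------------------------------------------------------------
# skew-normal
# ---------------------------------------------------------------------------


def _check_finite(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    return y


def sn_logpdf(y, p: SkewNormalDP):
    """Log density of SN(xi, sigma^2, psi); vectorized in ``y``."""
    y = _check_finite(y)
    z = (y - p.xi) / p.sigma
    # log[2 phi(z) Phi(psi z) / sigma]; log_ndtr is tail-stable
    out = (
        _LOG_2
        - math.log(p.sigma)
        - 0.5 * (z * z + math.log(2.0 * math.pi))
        + special.log_ndtr(p.psi * z)
    )
    return out if out.shape else float(out)


def sn_pdf(y, p: SkewNormalDP):
    """Density (2/sigma) phi(z) Phi(psi z)."""
    out = np.exp(sn_logpdf(y, p))
    return out if np.ndim(out) else float(out)


def sn_cdf(y, p: SkewNormalDP):
    """Distribution function via the Owen's-T identity F(z) = Phi(z) - 2 T(z, psi)."""
    y = _check_finite(y)
    z = (y - p.xi) / p.sigma
    out = special.ndtr(z) - 2.0 * special.owens_t(z, p.psi)
    out = np.clip(out, 0.0, 1.0)
    return out if out.shape else float(out)


def _sn_sf_quad(z: float, psi: float) -> float:
    """Upper-tail probability of the standardized SN by adaptive quadrature.

    Used when the Owen's-T expression loses precision (negative-psi right
    tail, where Phi(-z) and 2 T(z, psi) nearly cancel).
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(
            lambda u: 2.0
            * np.exp(-0.5 * u * u - 0.5 * math.log(2 * math.pi) + special.log_ndtr(psi * u)),
            z,
            z + 50.0,
            epsabs=0.0,
            epsrel=1e-11,
            limit=300,
        )
    return val


def sn_sf(y, p: SkewNormalDP):
    """Survival function P(Y > y) = Phi(-z) + 2 T(z, psi)."""
    y = _check_finite(y)
    z = np.atleast_1d((y - p.xi) / p.sigma)
    out = special.ndtr(-z) + 2.0 * special.owens_t(z, p.psi)
    # refine where cancellation dominated (psi < 0 deep right tail)
    tiny = (out < 1e-10) & (z > 0)
    if np.any(tiny) and p.psi < 0:
        for i in np.nonzero(tiny)[0]:
            out[i] = _sn_sf_quad(float(z[i]), p.psi)
    out = np.clip(out, 0.0, 1.0)
    return out if np.ndim(y) else float(out[0])


def sn_logsf(y, p: SkewNormalDP):
    """log P(Y > y), floored at log(1e-300)."""
    sf = np.atleast_1d(np.asarray(sn_sf(y, p), dtype=float))
    out = np.log(np.maximum(sf, 1e-300))
    return out if np.ndim(y) else float(out[0])


def sn_ppf(q, p: SkewNormalDP):
    """Quantile function of SN(xi, sigma^2, psi) by bracketed root-finding."""
    from scipy.optimize import brentq

    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("q must lie strictly inside (0, 1)")
    out = np.array(
        [
            brentq(lambda y, qq=qq: sn_cdf(y, p) - qq, p.xi - 12 * p.sigma,
                   p.xi + 12 * p.sigma, xtol=1e-10)
            for qq in np.atleast_1d(q)
        ]
    )
    return out if q.shape else float(out[0])


def sn_mean_var(p: SkewNormalDP) -> tuple[float, float]:
    """Mean and variance of SN(xi, sigma^2, psi).

    E(Y) = xi + sigma sqrt(2/pi) psi / sqrt(1 + psi^2),
    V(Y) = sigma^2 (1 - (2/pi) psi^2 / (1 + psi^2)).
    """
    d = p.psi / math.hypot(1.0, p.psi)
    mean = p.xi + p.sigma * _SQRT_2_PI * d
    var = p.sigma**2 * (1.0 - (2.0 / math.pi) * d * d)
    return mean, var


def sn_rvs(p: SkewNormalDP, n: int, rng) -> np.ndarray:
    """Draw ``n`` variates via the additive representation.

    With delta = psi / sqrt(1 + psi^2) and independent standard normals
    Z0, Z1:  Y = xi + sigma (delta |Z0| + sqrt(1 - delta^2) Z1).
    Exact and rejection-free.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    d = p.psi / math.hypot(1.0, p.psi)
    z0 = rng.standard_normal(n)
    z1 = rng.standard_normal(n)
    return p.xi + p.sigma * (d * np.abs(z0) + math.sqrt(1.0 - d * d) * z1)


def dp_to_cp(p: SkewNormalDP) -> SkewNormalCP:
    """Convert direct to centered parameters.

    gamma1 = ((4 - pi)/2) sign(psi) (psi^2 / (pi/2 + (pi/2 - 1) psi^2))^(3/2)
    with mu and s from the mean/variance formulas.
    """
    mean, var = sn_mean_var(p)
    # psi^2/(pi/2 + (pi/2-1) psi^2) == d2/(pi/2 - d2) with d2 = psi^2/(1+psi^2)
    d2 = p.psi**2 / (1.0 + p.psi**2)
    ratio = d2 / (math.pi / 2.0 - d2)
    gamma1 = 0.5 * (4.0 - math.pi) * math.copysign(ratio**1.5, p.psi)
    interior = np.nextafter(gamma1_max(), 0.0)  # huge |psi| rounds onto the bound
    return SkewNormalCP(mu=mean, s=math.sqrt(var), gamma1=float(np.clip(gamma1, -interior, interior)))


def cp_to_dp(c: SkewNormalCP) -> SkewNormalDP:
    """Exact inverse of :func:`dp_to_cp` (closed-form inversion).

    Writing mz = E[(Y - xi)/sigma] = sqrt(2/pi) delta, the skewness index is
    gamma1 = ((4-pi)/2) mz^3 / (1 - mz^2)^(3/2); solving for
    t = mz / sqrt(1 - mz^2) gives t^3 = 2 gamma1 / (4 - pi).
    """
    if abs(c.gamma1) > gamma1_max() - GAMMA1_MARGIN:
        raise ValueError(
            "|gamma1| too close to the skew-normal boundary for a stable "
            f"inversion (bound {gamma1_max() - GAMMA1_MARGIN:.6f})"
        )
    t = math.copysign(abs(2.0 * c.gamma1 / (4.0 - math.pi)) ** (1.0 / 3.0), c.gamma1)
    mz = t / math.hypot(1.0, t)
    delta = mz / _SQRT_2_PI
    if abs(delta) >= 1.0:
        raise ValueError("|gamma1| too close to the boundary")
    psi = delta / math.sqrt(1.0 - delta * delta)
    sigma = c.s / math.sqrt(1.0 - mz * mz)
    xi = c.mu - sigma * mz
    return SkewNormalDP(xi=xi, sigma=sigma, psi=psi)


# ---------------------------------------------------------------------------
# Gompertz
# ---------------------------------------------------------------------------


def _check_nonneg_t(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("t must be finite and >= 0")
    return t


def gompertz_logsf(t, p: GompertzParams):
    t = _check_nonneg_t(t)
    out = -(p.alpha / p.gamma) * np.expm1(p.gamma * t)
    return out if out.shape else float(out)


def gompertz_pdf_sf_hazard(t, p: GompertzParams):
    """(density, survival, hazard) of the Gompertz law at ``t >= 0``.

    hazard = alpha exp(gamma t);  S(t) = exp(-(alpha/gamma)(exp(gamma t)-1)).
    """
    t = _check_nonneg_t(t)
    hazard = p.alpha * np.exp(p.gamma * t)
    sf = np.exp(gompertz_logsf(t, p))
    pdf = hazard * sf
    if pdf.shape:
        return pdf, sf, hazard
    return float(pdf), float(sf), float(hazard)


def gompertz_mean(p: GompertzParams) -> float:
    """E(T) = (1/gamma) exp(alpha/gamma) E1(alpha/gamma) (exponential integral)."""
    r = p.alpha / p.gamma
    # exp(r) * E1(r) evaluated stably (scipy's exp1 underflow-safe for small r)
    return float(math.exp(r) * special.exp1(r) / p.gamma)


def gompertz_rvs(p: GompertzParams, n: int, rng) -> np.ndarray:
    """Inverse-cdf sampling: t = log1p(-(gamma/alpha) log U) / gamma."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    u = rng.random(n)
    return np.log1p(-(p.gamma / p.alpha) * np.log(u)) / p.gamma


# ---------------------------------------------------------------------------
# Weibull
# ---------------------------------------------------------------------------


def weibull_pdf_sf_hazard(t, p: WeibullParams):
    """(density, survival, hazard) of the Weibull law at ``t > 0``."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError("t must be finite and > 0")
    if p.gamma == 0:
        raise ValueError("Weibull hazard undefined for gamma = 0")
    z = t / p.alpha
    hazard = (p.gamma / p.alpha) * z ** (p.gamma - 1.0)
    sf = np.exp(-(z**p.gamma))
    pdf = hazard * sf
    if pdf.shape:
        return pdf, sf, hazard
    return float(pdf), float(sf), float(hazard)


def weibull_mean(p: WeibullParams) -> float:
    """E(T) = alpha * Gamma(1 + 1/gamma)."""
    if p.gamma == 0:
        raise ValueError("Weibull mean undefined for gamma = 0")
    return float(p.alpha * special.gamma(1.0 + 1.0 / p.gamma))


def weibull_rvs(p: WeibullParams, n: int, rng) -> np.ndarray:
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    return p.alpha * rng.weibull(p.gamma, size=n)


# ---------------------------------------------------------------------------
# Gompertz / skew-normal mixture
# ---------------------------------------------------------------------------


def mixture_rvs(
    pG: GompertzParams, pSN: SkewNormalDP, delta: float, n: int, rng
) -> np.ndarray:
    """Draws from m(x) = delta f_Gompertz(x) + (1 - delta) f_SN(x).

    Component membership is Bernoulli(delta) per draw.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    from_g = rng.random(n) < delta
    out = np.empty(n)
    ng = int(from_g.sum())
    if ng:
        out[from_g] = gompertz_rvs(pG, ng, rng)
    if n - ng:
        out[~from_g] = sn_rvs(pSN, n - ng, rng)
    return out
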