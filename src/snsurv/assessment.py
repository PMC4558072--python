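"""Goodness-of-fit and diagnostic surfaces.

* Pearson X^2 on one-year binned death counts, X^2 = sum (O - E)^2 / E,
  with expected counts renormalized over the assessed age window so that
  sum(E) = N (closed-window comparison; the degrees of freedom are reported
  as the interval count, 70 for ages 35-105, with a parameter-corrected
  alternative behind a flag).
* Log-hazard curves log lambda(t) = log f(t) - log S(t); for a Gompertz fit
  this is exactly affine in t, so curvature of another model's curve
  measures its departure from Gompertz behaviour.
* Residual quartile tables stratified by predicted outcome, and QQ points
  against the fitted skew-normal residual law (uncensored records only:
  censored residuals are one-sided and are excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import check_survival_y
from .distributions import SkewNormalCP, cp_to_dp, sn_ppf
from .estimation import _BaseCenteredRegression

__all__ = ["GofResult", "expected_deaths", "pearson_x2", "log_hazard_curve",
           "residual_diagnostics", "compare_models"]


@dataclass(frozen=True)
class GofResult:
    x2: float
    df: int
    per_interval: pd.DataFrame

    def __post_init__(self):
        if self.x2 < 0:
            raise ValueError("X^2 must be nonnegative")


def expected_deaths(fit, N, age_lo, age_hi, X=None, normalize=True,
                    time_offset=0.0) -> pd.DataFrame:
    """Expected one-year death counts E_i from a fitted model.

    E_i = N * [F(x+1) - F(x)] / [F(age_hi) - F(age_lo)] for one-year
    intervals [x, x+1), x = age_lo .. age_hi - 1, evaluated on the fit's own
    time scale (``time_offset`` is subtracted from attained ages first, e.g.
    35 for a remaining-age-from-35 model).  With ``normalize=False`` the
    unconditional mass N * [F(x+1) - F(x)] is returned instead.
    """
    if not age_hi > age_lo:
        raise ValueError("age_hi must exceed age_lo")
    edges = np.arange(age_lo, age_hi + 1, dtype=float) - time_offset
    sf = np.ravel(fit.survival_function(edges, X))
    cdf = 1.0 - sf
    mass = np.diff(cdf)
    denom = cdf[-1] - cdf[0]
    if normalize:
        if denom <= 0:
            raise ValueError("no fitted probability mass in the age window")
        expected = N * mass / denom
    else:
        expected = N * mass
    return pd.DataFrame({"age": np.arange(age_lo, age_hi), "expected": expected})


def _merge_zero_expected(ages, observed, expected):
    """Merge zero-expected intervals into their left neighbour (df shrinks)."""
    a, o, e = [], [], []
    for age, obs, exp in zip(ages, observed, expected):
        if e and exp == 0:
            o[-1] += obs
            continue
        if e and e[-1] == 0:  # leading zeros merge forward
            o[-1] += obs
            e[-1] += exp
            continue
        a.append(age)
        o.append(obs)
        e.append(exp)
    return np.asarray(a), np.asarray(o, float), np.asarray(e, float)


def pearson_x2(observed, expected, ages=None) -> GofResult:
    """Pearson X^2 = sum (O - E)^2 / E over one-year intervals.

    df is reported as the number of intervals (mirroring the closed-window
    convention); intervals with zero expected count are merged into a
    neighbour and df reduced accordingly.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have equal length")
    if np.any(expected < 0):
        raise ValueError("expected counts must be nonnegative")
    if ages is None:
        ages = np.arange(observed.size)
    ages, observed, expected = _merge_zero_expected(ages, observed, expected)
    if np.any(expected == 0):
        raise ValueError("expected counts are all zero")
    x2 = float(np.sum((observed - expected) ** 2 / expected))
    per = pd.DataFrame({"age": ages, "observed": observed, "expected": expected})
    return GofResult(x2=x2, df=int(len(expected)), per_interval=per)


def log_hazard_curve(fit, ages, X=None, time_offset=0.0) -> pd.DataFrame:
    """Pointwise log hazard log f - log S on an age grid.

    Grid points where the fitted survival has underflowed (S < 1e-12) are
    dropped with a warning.
    """
    ages = np.asarray(ages, dtype=float)
    t = ages - time_offset
    sf = np.ravel(fit.survival_function(t, X))
    keep = sf > 1e-12
    if not np.all(keep):
        warnings.warn("grid truncated where fitted survival underflows")
    logpdf = np.ravel(fit.log_density(t[keep], X))
    out = logpdf - np.log(sf[keep])
    return pd.DataFrame({"age": ages[keep], "log_hazard": out})


def residual_diagnostics(fit, X, y, n_strata=10):
    """Residual quartile table and skew-normal QQ points.

    Residuals are y_i - E(Y|X_i) for uncensored records (censored residuals
    are one-sided and excluded).  Quartiles are tabulated per stratum of the
    predicted outcome; QQ points compare sorted residuals to quantiles of
    the fitted mean-zero residual law SN_CP(0, s, gamma1).
    """
    if not isinstance(fit, _BaseCenteredRegression):
        raise TypeError("residual diagnostics are defined for the CP-scale fits")
    entry, time, event = check_survival_y(y)
    obs = event == 1
    if not np.any(obs):
        raise ValueError("no uncensored records: residuals unavailable")
    pred = np.ravel(fit.predict(X))
    if pred.size == 1:
        pred = np.full(time.shape, pred[0])
    resid = (time - pred)[obs]
    pred = pred[obs]

    uniq = np.unique(pred)
    if uniq.size == 1:
        strata = np.zeros(pred.size, dtype=int)
        n_strata = 1
    else:
        qs = np.quantile(pred, np.linspace(0, 1, n_strata + 1))
        qs[0], qs[-1] = -np.inf, np.inf
        strata = np.searchsorted(qs, pred, side="right") - 1
    rows = []
    for s in range(n_strata):
        r = resid[strata == s]
        if r.size == 0:
            continue
        q1, med, q3 = np.quantile(r, [0.25, 0.5, 0.75])
        rows.append({"stratum": s, "n": r.size, "q1": q1, "median": med, "q3": q3})
    quartiles = pd.DataFrame(rows)

    resid_cp = SkewNormalCP(0.0, fit.sd_, fit.skew_)
    dp0 = cp_to_dp(resid_cp)
    n = resid.size
    pp = (np.arange(1, n + 1) - 0.5) / n
    qq = pd.DataFrame(
        {"theoretical": sn_ppf(pp, dp0), "sample": np.sort(resid)}
    )
    return {"quartiles": quartiles, "qq": qq}


def compare_models(ages_at_death, age_lo=35.0, age_hi=105.0):
    """Fit all six life-expectancy models to uncensored ages at death.

    The hypothetical-population comparison: individual ages at death (no
    censoring, no delayed entry) are fitted with Weibull PH, Gompertz PH,
    Weibull AFT, log-normal AFT (on remaining age since ``age_lo``) and the
    skew-normal and Gaussian regressions (on attained age).  Returns a
    DataFrame with remaining life expectancy at ``age_lo`` and the Pearson
    X^2 on one-year binned deaths, one row per model.
    """
    from .data import make_survival_y
    from .estimation import GaussianSurvivalRegression, SkewNormalSurvivalRegression
    from .life_expectancy import remaining_le
    from .survival_models import ParametricAFTRegression, ParametricPHRegression

    ages = np.asarray(ages_at_death, dtype=float)
    t_rem = ages - age_lo
    y_rem = make_survival_y(t_rem)
    y_att = make_survival_y(ages)

    edges = np.arange(age_lo, age_hi + 1)
    observed, _ = np.histogram(ages, bins=edges)
    N = int(observed.sum())

    fits = {
        "ph_weibull": (ParametricPHRegression("weibull").fit(None, y_rem), age_lo),
        "ph_gompertz": (ParametricPHRegression("gompertz").fit(None, y_rem), age_lo),
        "aft_weibull": (ParametricAFTRegression("weibull").fit(None, y_rem), age_lo),
        "aft_lognormal": (ParametricAFTRegression("lognormal").fit(None, y_rem), age_lo),
        "skew_normal": (SkewNormalSurvivalRegression().fit(None, y_att), 0.0),
        "gaussian": (GaussianSurvivalRegression().fit(None, y_att), 0.0),
    }
    rows = []
    for tag, (fit, offset) in fits.items():
        exp = expected_deaths(fit, N, age_lo, age_hi, time_offset=offset)
        gof = pearson_x2(observed, exp["expected"].to_numpy(), ages=exp["age"].to_numpy())
        rows.append(
            {
                "model": tag,
                "rle": remaining_le(fit, at_age=age_lo),
                "x2": gof.x2,
                "df": gof.df,
                "loglik": fit.loglik_,
                "converged": fit.converged_,
            }
        )
    return pd.DataFrame(rows).set_index("model")
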