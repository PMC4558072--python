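"""Hypothetical populations from one-year death rates, and synthetic cohorts.

The life-table construction follows the hypothetical-population recipe:
starting from a radix of N persons alive at the first age, the deaths in the
one-year interval [x, x+1) are n_x = m_x * l_x, with l_{x+1} = l_x - n_x
(m_x treated as the per-interval death probability; no actuarial a_x
adjustment).  Deaths are kept as real numbers; conversion to individual
ages at death assigns within-interval ages uniformly (midpoint optional)
with nearest or stochastic rounding of the interval counts.

:func:`generate_cohort` emulates a census-based cohort design: subjects
enter at their age on a census date and are followed for a fixed
administrative window, so observation is left-truncated at the entry age
(realized here by rejection of subjects already dead at entry) and
type-I-censored at the end of follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import make_survival_y
from .distributions import (
    GompertzParams,
    SkewNormalCP,
    SkewNormalDP,
    cp_to_dp,
    gompertz_rvs,
    mixture_rvs,
    sn_rvs,
)

__all__ = ["LifeTable", "CohortConfig", "build_lifetable", "read_rate_table",
           "lifetable_to_individuals", "generate_cohort"]


@dataclass(frozen=True)
class LifeTable:
    """One-year life table: interval starts, rates, survivors, deaths."""

    ages: np.ndarray
    m_x: np.ndarray
    l_x: np.ndarray
    n_x: np.ndarray

    @property
    def radix(self) -> float:
        return float(self.l_x[0])

    @property
    def survivors_at_end(self) -> float:
        return float(self.l_x[0] - self.n_x.sum())

    def mean_age_at_death(self) -> float:
        """Interval-midpoint mean age among deaths in the table."""
        return float(np.sum(self.n_x * (self.ages + 0.5)) / np.sum(self.n_x))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "mx": self.m_x, "lx": self.l_x, "nx": self.n_x}
        )


def build_lifetable(rates, N=100_000) -> LifeTable:
    """Deaths per one-year interval from death rates: n_x = m_x * l_x.

    ``rates`` is a DataFrame (columns age, mx) or a (age, mx) array; ages
    must be contiguous one-year interval starts and every m_x a per-interval
    probability in [0, 1].
    """
    if isinstance(rates, pd.DataFrame):
        ages = rates["age"].to_numpy(float)
        mx = rates["mx"].to_numpy(float)
    else:
        arr = np.asarray(rates, dtype=float)
        ages, mx = arr[:, 0], arr[:, 1]
    if N <= 0:
        raise ValueError("N must be positive")
    if not np.allclose(np.diff(ages), 1.0):
        raise ValueError("ages must be contiguous one-year interval starts")
    if np.any((mx < 0) | (mx > 1)):
        raise ValueError("death rates must lie in [0, 1] (per-interval probabilities)")
    lx = np.empty(mx.size)
    nx = np.empty(mx.size)
    alive = float(N)
    for i, m in enumerate(mx):
        lx[i] = alive
        nx[i] = m * alive
        alive -= nx[i]
    return LifeTable(ages=ages.astype(int), m_x=mx, l_x=lx, n_x=nx)


def read_rate_table(path, sex=None, age_lo=35, age_hi=105, sep=None) -> pd.DataFrame:
    """Read a one-year death-rate table.

    Accepts either the package's two-column format (age, mx) or the HMD
    Mx_1x1 layout (Age, Female, Male, Total; ``sex`` selects the column).
    Open age groups like "110+" are rejected above the cap and the table is
    clipped to [age_lo, age_hi).
    """
    df = pd.read_csv(path, sep=sep, engine="python", skipinitialspace=True)
    cols = {c.lower(): c for c in df.columns}
    if "mx" in cols and "age" in cols:
        out = df.rename(columns={cols["age"]: "age", cols["mx"]: "mx"})[["age", "mx"]]
    elif "age" in cols and sex is not None and sex.lower() in cols:
        out = df.rename(columns={cols["age"]: "age", cols[sex.lower()]: "mx"})[
            ["age", "mx"]
        ]
    else:
        raise ValueError(
            "rate table needs columns (age, mx) or HMD columns (Age, Female, "
            "Male, Total) with sex= given"
        )
    age_num = pd.to_numeric(out["age"], errors="coerce")
    open_ended = age_num.isna()
    if open_ended.any():
        bad_ages = out.loc[open_ended, "age"].astype(str)
        if any(int(a.rstrip("+")) < age_hi for a in bad_ages if a.rstrip("+").isdigit()):
            raise ValueError("open age group below the age cap")
        out = out[~open_ended]
        age_num = age_num[~open_ended]
    out = out.assign(age=age_num.astype(int))
    out = out[(out["age"] >= age_lo) & (out["age"] < age_hi)].reset_index(drop=True)
    out["mx"] = pd.to_numeric(out["mx"], errors="raise")
    return out


def lifetable_to_individuals(lt: LifeTable, random_state=None, rounding="nearest",
                             within="uniform") -> np.ndarray:
    """Individual ages at death from a life table, one per (rounded) death.

    ``rounding``: "nearest" or "stochastic" (fractional deaths become an
    extra death with probability equal to the fraction).  ``within``:
    "uniform" spreads ages uniformly on [x, x+1); "midpoint" uses x + 0.5.
    Survivors past the final interval are dropped (with a warning when any).
    """
    rng = np.random.default_rng(random_state)
    if rounding == "stochastic":
        frac = lt.n_x - np.floor(lt.n_x)
        counts = np.floor(lt.n_x).astype(int) + (rng.random(lt.n_x.size) < frac)
    elif rounding == "nearest":
        counts = np.round(lt.n_x).astype(int)
    else:
        raise ValueError("rounding must be 'nearest' or 'stochastic'")
    if lt.survivors_at_end > 0.5:
        import warnings

        warnings.warn(
            f"{lt.survivors_at_end:.1f} survivors beyond the final interval dropped"
        )
    ages = np.repeat(lt.ages.astype(float), counts)
    if within == "uniform":
        ages = ages + rng.random(ages.size)
    elif within == "midpoint":
        ages = ages + 0.5
    else:
        raise ValueError("within must be 'uniform' or 'midpoint'")
    return ages


def gompertz_makeham_rates(age_lo=35, age_hi=105, background=5e-4,
                           alpha=np.exp(-12.25), gamma=0.116) -> pd.DataFrame:
    """Synthetic one-year adult death rates (Gompertz-Makeham law).

    A stand-in for a real national rate table: per-interval death
    probabilities m_x = 1 - exp(-(background + alpha*exp(gamma*(x+0.5)))).
    The defaults mimic modern European adult mortality (senescent hazard doubling
    roughly every six years over a small accident background); real tables
    additionally carry cohort effects and a young-adult hump that this
    synthetic law does not.
    """
    ages = np.arange(age_lo, age_hi)
    hazard = background + alpha * np.exp(gamma * (ages + 0.5))
    return pd.DataFrame({"age": ages, "mx": -np.expm1(-hazard)})


@dataclass(frozen=True)
class CohortConfig:
    """Settings for a synthetic censored, left-truncated cohort.

    ``truth`` is "gompertz", "skew_normal" or "mixture" (with ``delta`` the
    Gompertz weight).  Latent ages at death are drawn on the attained-age
    scale; subjects enter at an age drawn from a Beta(entry_beta) law scaled
    to ``entry_age_range`` (roughly the decreasing adult age pyramid of a
    census), are discarded if already dead at entry (left truncation by
    rejection), and are censored ``follow_up_years`` after entry (the
    administrative window; 8.07 years spans 5 Dec 2000 - 31 Dec 2008).
    ``covariates`` maps a name to (prevalence, effect_years): Bernoulli
    covariates shifting the location of the latent death age.
    """

    n_subjects: int
    truth: str = "skew_normal"
    gompertz: GompertzParams = GompertzParams(alpha=np.exp(-12.25), gamma=0.116)
    skew_normal: SkewNormalCP = SkewNormalCP(82.1, 11.1, -0.836)
    delta: float = 0.5
    follow_up_years: float = 8.07
    entry_age_range: tuple = (35.0, 105.0)
    entry_beta: tuple = (1.2, 2.0)
    covariates: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.follow_up_years <= 0:
            raise ValueError("follow_up_years must be positive")
        if self.truth not in ("gompertz", "skew_normal", "mixture"):
            raise ValueError(f"unknown truth {self.truth!r}")


def _draw_latent(cfg: CohortConfig, n, rng):
    dp = cp_to_dp(cfg.skew_normal)
    if cfg.truth == "gompertz":
        return gompertz_rvs(cfg.gompertz, n, rng)
    if cfg.truth == "skew_normal":
        return sn_rvs(dp, n, rng)
    return mixture_rvs(cfg.gompertz, dp, cfg.delta, n, rng)


def generate_cohort(cfg: CohortConfig):
    """Synthetic cohort; returns (X or None, y, info dict).

    y is the (n, 3) [entry, time, event] target on the attained-age scale;
    info reports the realized censoring proportion and the truncation
    (rejection) rate.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.entry_age_range
    names = list(cfg.covariates)
    accepted = []
    n_drawn = 0
    while sum(a[0].size for a in accepted) < cfg.n_subjects:
        m = max(2 * cfg.n_subjects, 1000)
        n_drawn += m
        entry = lo + (hi - lo) * rng.beta(*cfg.entry_beta, size=m)
        covs = np.column_stack(
            [rng.random(m) < cfg.covariates[c][0] for c in names]
        ).astype(float) if names else np.empty((m, 0))
        shift = covs @ np.asarray([cfg.covariates[c][1] for c in names]) if names else 0.0
        death = _draw_latent(cfg, m, rng) + shift
        keep = death >= entry
        accepted.append((entry[keep], death[keep], covs[keep]))
        if n_drawn >= 100 * cfg.n_subjects and sum(a[0].size for a in accepted) < 0.01 * n_drawn:
            raise ValueError("truth parameters leave <1% of subjects alive at entry")
    entry = np.concatenate([a[0] for a in accepted])[: cfg.n_subjects]
    death = np.concatenate([a[1] for a in accepted])[: cfg.n_subjects]
    covs = np.concatenate([a[2] for a in accepted])[: cfg.n_subjects]
    n_accepted_total = sum(a[0].size for a in accepted)

    censor_age = entry + cfg.follow_up_years
    event = (death <= censor_age).astype(float)
    exit_age = np.minimum(death, censor_age)
    y = make_survival_y(time=exit_age, event=event, entry=entry)
    X = pd.DataFrame(covs, columns=names) if names else None
    info = {
        "censoring_proportion": float(1.0 - event.mean()),
        "rejection_rate": float(1.0 - n_accepted_total / n_drawn),
        "n": int(cfg.n_subjects),
    }
    return X, y, info
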