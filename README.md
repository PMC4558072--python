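# snsurv

Censored, left-truncated **skew-normal survival regression** for modelling
absolute differences in life expectancy, with the standard parametric
survival comparators (Weibull/Gompertz proportional hazards, Weibull and
log-normal accelerated failure time), life-table cohort synthesis,
goodness-of-fit diagnostics, and a model-misspecification coverage study.

## The problem

Proportional-hazards and accelerated-failure-time models report covariate
effects as hazard ratios or time ratios — neither is directly a difference
in years of life. A Gaussian regression of age at death *is* in years, but
adult lifespans are negatively skewed, so its assumptions fail. The
skew-normal law SN(ξ, σ², ψ), with density

    g(y; ξ, σ², ψ) = (2/σ) φ((y−ξ)/σ) Φ(ψ (y−ξ)/σ),

extends the Gaussian with a shape parameter ψ and captures that skewness
while keeping regression coefficients on the year scale. Two complications
of census-based mortality cohorts are built into the likelihood:

* **right censoring** (type I): subjects alive at the administrative end of
  follow-up contribute S(c_i);
* **delayed entry / left truncation**: subjects are observed only if alive
  at their entry age D_i, so every contribution is divided by S(D_i).

Fitting uses the **centered parametrization** (μ, s, γ₁) = (mean, SD,
skewness index), which removes the likelihood singularity at ψ = 0 and —
crucially — makes the fitted location parameter equal the mean, so μ̂ and
its Wald interval are estimates of mean life expectancy directly, and each
regression coefficient is a difference in expected years of life.

The package is written scikit-learn style: `SkewNormalSurvivalRegression`,
`GaussianSurvivalRegression`, `ParametricPHRegression` and
`ParametricAFTRegression` are estimators with `fit`/`predict`,
`get_params`/`set_params` and trailing-underscore fitted attributes; the
survival target is `[entry, time, event]` per row.

## Worked example

A synthetic census-style cohort (50,000 subjects, ~90% censored after an
8-year follow-up window, delayed entry at the census age, one binary
covariate shifting mean lifespan by +6 years):

```python
import numpy as np
from snsurv import fit_censored_sn, standard_errors, remaining_le
from snsurv.lifetable import CohortConfig, generate_cohort

cfg = CohortConfig(n_subjects=50_000, seed=42, covariates={"female": (0.5, 6.0)})
X, y, info = generate_cohort(cfg)
print(f"censoring proportion: {info['censoring_proportion']:.3f}")

fit = fit_censored_sn(y, X=X)
print(standard_errors(fit).round(3))
print(f"remaining life expectancy at 35 (reference): "
      f"{remaining_le(fit, X=[[0.0]], at_age=35.0):.2f} years")
```

prints

```
censoring proportion: 0.895
        estimate     se  ci_low  ci_high
mu        82.045  0.174  81.703   82.386
s         11.284  0.107  11.074   11.495
gamma1    -0.848  0.018  -0.883   -0.812
beta0      6.166  0.247   5.681    6.650
remaining life expectancy at 35 (reference): 47.04 years
```

The generating truth was CP mean 82.1, SD 11.1, skewness −0.836 and a
covariate effect of 6.0 years: all recovered within two standard errors
despite 89.5% of subjects being censored. `beta0` reads directly as "the
female group lives on average 6.2 years longer (95% CI 5.7–6.7)" — no
hazard-ratio translation needed.

A command-line interface mirrors the library (`snsurv fit`,
`snsurv lifetable`, `snsurv simulate`, `snsurv gof`); all randomness is
controlled by `--seed`.

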