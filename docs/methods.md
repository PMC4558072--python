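# Methods

## Model

Observed for subject i: an entry age D_i (delayed entry; `-inf` means
observed from the time origin), an exit age y_i = min(Y_i, C_i), a death
indicator δ_i, and a covariate row X_i. The skew-normal regression assumes

    Y_i = μ + X_i'β + ε_i,   ε_i ~ SN with mean 0, SD s, skewness index γ₁,

in the centered parametrization (CP). The log-likelihood is

    Σ_i [ δ_i log g(y_i | X_i) + (1 − δ_i) log S(y_i | X_i) − log S(D_i | X_i) ],

where g and S are the skew-normal density and survival function whose CP
location is μ + X_i'β. Censoring is non-informative type I (the
administrative censoring age is used as c_i directly); interval censoring
is out of scope. The truncation denominator is the unconditional S(D_i) —
conditioning the denominator on the event it defines would be vacuous.

Assumptions: covariates shift the location only (common s and γ₁ across
covariate levels); residuals are independent; the support is the whole
real line, so an ill-behaved fit can in principle put mass at impossible
ages (a known limitation of Gaussian-type lifespan models, relevant when
most deaths are very young).

## Parametrizations

The direct parametrization (DP) (ξ, σ, ψ) appears in the density; its
profile likelihood is singular at ψ = 0 and the MLE behaves badly near it.
The CP (μ, s, γ₁) is a smooth bijection of the DP (for γ₁ ≠ ±γ_max) given
by the moment identities

    E(Y) = ξ + σ √(2/π) ψ/√(1+ψ²),   V(Y) = σ² (1 − (2/π) ψ²/(1+ψ²)),
    γ₁  = ((4−π)/2) sign(ψ) (ψ²/(π/2 + (π/2−1)ψ²))^{3/2}.

The inversion is closed-form: with t³ = 2γ₁/(4−π), the standardized mean
is m_z = t/√(1+t²), δ = m_z √(π/2), ψ = δ/√(1−δ²), σ = s/√(1−m_z²),
ξ = μ − σ m_z. The admissible skewness bound γ_max ≈ 0.99527 is computed
as the ψ → ∞ limit of the identity above, never hard-coded; all CP inputs
to the inversion are required to stay 1e−4 inside it, because σ and ψ
diverge at the boundary.

## Numerics

* **Distribution function.** F(z) = Φ(z) − 2·T(z, ψ) with Owen's T
  (`scipy.special.owens_t`). The survival form Φ(−z) + 2 T(z, ψ) cancels
  catastrophically in the short (light) tail when ψ < 0; whenever the
  result falls below 1e−10 it is recomputed by adaptive quadrature of the
  density with a relative tolerance of 1e−11. Inside likelihoods, survival
  probabilities are floored at 1e−300 and any floored term is counted on
  the fitted object (`n_floored_`); direct likelihood evaluation raises
  instead, since a subject who "cannot" have survived to entry signals
  incompatible parameters.
* **Sampling.** The additive representation
  ξ + σ(δ_ψ|Z₀| + √(1−δ_ψ²) Z₁), δ_ψ = ψ/√(1+ψ²): exact and
  rejection-free. Gompertz variates use the closed-form inverse CDF.
  All randomness flows through `numpy.random.Generator`s; the simulation
  study spawns one child `SeedSequence` per scenario and per replicate
  from the root seed, so every replicate stream is independent and the
  whole study is reproducible bit-for-bit.
* **Optimization.** L-BFGS-B on (μ, log s, γ₁, β) with γ₁ box-constrained
  inside the admissible interval; gradient tolerance 1e−6, relative
  function tolerance 1e−12, starting values from (censoring-unadjusted)
  moments with moment skewness clipped to 0.9 of the bound and β = 0. The
  fitted log-likelihood is checked (in tests) to never fall below the
  starting value. PH/AFT fits optimize (log α, log γ, β) and
  (m, log σ, β) respectively.
* **Covariance.** Inverse of a central-finite-difference Hessian at the
  optimum, with steps proportional to each parameter's magnitude
  (parameters span many orders of magnitude — a Gompertz α is ~1e−5).
  Reported on the scale the model was optimized on: the CP scale for the
  skew-normal/Gaussian fits (so the SE of μ is the SE of the mean), the
  log scale for positivity-constrained PH/AFT parameters. A
  non-positive-definite Hessian withholds the covariance and the fit
  counts as failed in simulation summaries.

## Life expectancy

E(T|X) = ∫₀^∞ S(t|X) dt, evaluated in closed form: Weibull
α Γ(1+1/γ) (PH covariates scale α by exp(−X'β/γ)); Gompertz
(1/γ) e^{α/γ} E₁(α/γ) via the exponential integral (PH covariates scale
α); log-normal AFT exp(m + X'β + σ²/2); skew-normal: the CP location
μ + X'β *is* the mean (no truncation applied — the ≥35 condition of an
adult cohort is already built into the fit through the likelihood's
truncation terms; a conditional version E(Y | Y ≥ a) − a by quadrature is
available behind `conditional=True`). Every closed form is verified
against quadrature of the fitted survival function at 1e−6 relative
tolerance in the test suite.

Confidence intervals for E(T|X) are percentile intervals from draws of
the parameter vector ~ MVN(estimates, covariance), 10,000 draws by
default (1,000 inside the simulation study as a cost/accuracy
compromise). Draws violating parameter constraints are rejected and
counted; more than 50% rejections is an error. Sampling happens on the
optimized scale: for PH/AFT models that is the log scale, where every
draw is valid. Sampling the natural (α, γ) scale instead was evaluated
and rejected: at n = 100 the Gaussian approximation for α ~ 1e−5 is so
poor that coverage of the Gompertz-mean interval drops from ~0.94 to
~0.80.

For the skew-normal mean specifically, the CP location's Wald interval
μ̂ ± 1.96·SE(μ̂) is used in the simulation study — the location *is* the
mean, so no resampling is needed.

## Goodness of fit

Expected one-year death counts E_x = N·[F(x+1) − F(x)] / [F(hi) − F(lo)]
are renormalized over the assessed window (35–105 by default), so
ΣE = ΣO and the Pearson statistic X² = Σ(O−E)²/E compares shapes on a
closed window; the degrees of freedom are reported as the interval count
(70), matching the closed-window convention, with zero-expected intervals
merged into a neighbour. Log-hazard curves log f − log S are emitted as
tidy (age, value) tables; a Gompertz fit's curve is exactly affine with
slope γ, so curvature of another model's curve measures departure from
Gompertz behaviour. Residual diagnostics (quartiles per decile of the
prediction, QQ points against the fitted mean-zero skew-normal law) use
uncensored records only — censored residuals are one-sided, a documented
limitation.

## Synthetic data

Two generators stand in for restricted real data sources; both are
first-class, tested code.

* `gompertz_makeham_rates` builds a one-year adult death-rate table from
  a Gompertz–Makeham hazard (background 5e−4, senescent component with
  shape 0.116 and scale exp(−12.25), i.e. hazard doubling roughly every
  six years). It mimics the *shape* of a modern national adult mortality
  schedule but carries no cohort effects and no young-adult accident
  hump, so tests built on it demonstrate pipeline correctness and the
  qualitative model ordering, not agreement with any particular country's
  published values.
* `build_lifetable` turns rates into a deterministic hypothetical
  population by the recursion n_x = m_x·l_x, l_{x+1} = l_x − n_x from a
  radix of 100,000 — m_x is treated as a per-interval death probability
  (no actuarial a_x adjustment), deaths stay fractional until
  individual-level conversion, which assigns within-interval ages
  uniformly (midpoint optional) with nearest or stochastic rounding.
* `generate_cohort` emulates a census-based cohort: entry ages are drawn
  from a Beta(1.2, 2.0) law scaled to [35, 105] — a stylized decreasing
  adult age pyramid chosen once so that, combined with an 8.07-year
  administrative follow-up window and the default skew-normal lifespan
  law, roughly 88% of subjects are censored, the regime of interest for
  census mortality studies. Left truncation is realized by rejection
  (subjects dead before entry are never observed). Real cohorts
  additionally have emigration, linkage error and period effects; none
  are modelled.

## Simulation study

Truths: Gompertz (shape 0.116, scale exp(−12.25); mean 82.06 by the
exponential-integral form, cross-checked by two independent quadratures),
skew-normal (CP 82.1, 11.1, −0.836; mean 82.1 by construction), and
mixtures δ·Gompertz + (1−δ)·skew-normal with δ ∈ {0.1, 0.25, 0.5, 0.75,
0.9}. Samples are drawn untruncated and uncensored. Per replicate both
models are fitted and a 95% interval for the distribution mean computed
(Wald on the CP location; MVN-percentile for the Gompertz mean); the
scenario summary is the coverage proportion over converged fits (failure
counts reported, a scenario with >5% failures is flagged) and the mean ±
SD of the bias. **Bias is estimated mean − true mean**; a `sign` flag
flips the convention for comparison with tables that define it the other
way around.

Problem sizes: the package's acceptance runs use 400 replicates for the
n = 10,000 scenarios and 1,000 replicates for n ∈ {100, 1,000}; the full
grid at 1,000 replicates is available through `full_study_scenarios` /
`snsurv simulate`.

## Known limitations

* Covariate effects on scale or shape, frailty, interval censoring and
  time-varying covariates are not supported.
* DP-scale standard errors are not reported (the covariance is CP-scale).
* Under mixture truths that are predominantly Gompertz, the skew-normal
  model's misspecification bias grows roughly linearly in the Gompertz
  weight (to about −0.15 years at the pure-Gompertz end under the default
  truth parameters) and, because the bias is stable while the SE shrinks,
  its nominal-95% interval undercovers progressively as n grows — the
  study's central cautionary finding. Published tabulations of this decay
  exist that are substantially flatter in δ than what exact KL-projection
  arithmetic (and this implementation) yields at δ ≥ 0.5; the test suite
  pins the behaviour of *this* implementation and documents the
  discrepancy where it asserts external values.
* The bimodal shape of full-lifespan (birth-to-death) mortality is out of
  scope; all defaults target adult (35+) mortality.
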