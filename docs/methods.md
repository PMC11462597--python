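# Methods

## The model

`spataft` fits Bayesian accelerated failure time (AFT) models to
right-censored, georeferenced survival data.  For patient *j* in region
*i*,

    log T_ij = mu + beta' x_ij + W_i + rho * eps_ij

where `T_ij` is survival time (months), `x_ij` the vector of
treatment-contrast covariate indicators, `mu` the intercept (location of
log time at the reference covariate pattern), `rho > 0` the scale of the
log-time error, and `W_i` a region-level spatial frailty.  The three
baseline families correspond to the canonical error laws:

| family       | eps distribution        | T distribution at x = 0, W = 0     |
|--------------|-------------------------|------------------------------------|
| weibull      | standard minimum Gumbel | Weibull(shape 1/rho, scale e^mu)   |
| lognormal    | standard normal         | log-normal(mu, rho)                |
| loglogistic  | standard logistic       | log-logistic (Fisk), median e^mu   |

Right censoring enters the likelihood in the usual way: events contribute
`log f(t)`, censored records `log S(t)`.  The log-normal survival tail is
evaluated with `scipy`'s complementary normal CDF in log space (stable to
|z| of about 38); the log-logistic through a softplus.

A positive `beta_k` lengthens survival times.  Effect tables report
`exp(-beta/rho)` as the hazard-direction ratio (labelled AHR; the exact
proportional-hazards correspondence for the Weibull family and the
event-odds direction for the log-logistic) together with the time ratio
`exp(beta)`.  The two are monotone opposites for every posterior draw, so
the significance flag (95% credible interval excluding 1) agrees between
them.

## Spatial prior

Frailties carry an intrinsic conditional autoregressive (ICAR) prior on
the region contiguity graph (binary queen weights: regions sharing any
boundary point are neighbours).  Conditionally,

    W_i | W_{-i}, tau2  ~  N( mean of neighbour values , tau2 / m_i )

with `m_i` the neighbour count.  Jointly this is the improper
pairwise-difference Gaussian with precision `(D - A)/tau2`, proper on the
sum-to-zero subspace of each connected graph component (rank `R - k` for
`R` regions in `k` components).  Identifiability of `mu` versus the
frailty level is enforced by recentring `W` to component-wise zero mean
after every sweep, with the intercept absorbing the shift.

Islands (regions with no neighbours) have no ICAR conditional; they
receive an exchangeable `N(0, tau2)` prior and are excluded from the
pairwise-difference sum.  An optional unstructured (exchangeable) add-on
for all regions — the convolution model — is not enabled by default: the
fitted model has a single structured frailty term.

## Inference

Metropolis-within-Gibbs, one chain by default.  Per iteration:

1. scalar random-walk Metropolis on `mu` and each `beta_k`;
2. random-walk Metropolis on `log rho`;
3. single-site Metropolis on each `W_i` with target (region likelihood ×
   ICAR full conditional), then recentring.  The sweep is blocked by
   greedy graph colouring: within a colour class no two regions are
   adjacent, so their full conditionals are mutually independent given
   the rest and a whole class can be proposed and accepted/rejected at
   once.  This is algebraically the sequential single-site scheme in a
   fixed order, vectorised for speed;
4. conjugate inverse-gamma Gibbs draw of `tau2` with shape
   `a + (R - k)/2 + n_islands/2` and rate
   `b + (1/2) sum_edges (W_i - W_j)^2 + (1/2) sum_islands W_i^2`.

Proposal scales are tuned by Robbins-Monro during burn-in toward 35%
acceptance and frozen afterwards, preserving detailed balance in the
monitored phase.  The default schedule is burn-in 5000, 10,000 monitored
iterations, keeping every fourth; the command-line default is a
scaled-down schedule (burn 1000 / monitor 2000 / thin 2) with the full
protocol behind `--full-schedule`.  Chains are deterministic given the
seed.

Priors are weakly informative and overridable: `beta, mu ~ N(0, 10^2)`,
`log rho ~ N(0, 1)`, `tau2 ~ InverseGamma(0.5, 0.05)`.  Initialisation:
`mu` at the mean log event time, `beta = 0`, `rho = 1`, `W = 0`,
`tau2 = 0.1`.

Convergence diagnostics: effective sample size by Geyer's initial
monotone sequence estimator, Geweke z-scores (first 10% vs last 50% with
ESS-adjusted variances), and exported trace series.  Constant chains are
flagged degenerate rather than erroring.

## Model comparison and goodness of fit

DIC, WAIC and LPML are computed from the stored draws, conditioning on
the frailties (`W` treated as parameters — the usual convention for
frailty models).  The DIC plug-in deviance uses posterior means of
`(mu, beta, log rho, W)`; WAIC uses per-observation log-mean-exp and
variance of the pointwise log-likelihood; CPO is computed through the
stabilised log-space harmonic-mean identity, `LPML = sum_i log CPO_i`.
Negative effective-parameter estimates are reported with a warning, not
hidden.  The comparison harness fits an arbitrary candidate grid (family
× spatial × covariates) under a shared seed policy and ranks by DIC,
reporting all three criteria; a failed candidate is recorded in its row
and the comparison continues.

Cox-Snell residuals `r = -log S(t | posterior means)` check calibration:
for the true model, residuals of event times are unit exponential and
censored records yield censored residuals.  The package reports the
Nelson-Aalen cumulative hazard of the residuals against the residuals,
plus the through-origin least-squares slope ("slope one" criterion).
The plain Kolmogorov-Smirnov comparison of uncensored residuals with
Exp(1) is only valid without censoring: administrative censoring
truncates the observed residuals, so the KS-based checks in the test
suite and acceptance script run on fully observed simulations, while the
slope criterion (which handles censoring correctly through Nelson-Aalen)
runs under the censored study conditions.

## Synthetic cohorts

The generator emulates the structure of a state cancer-registry cohort
over local government areas, since such registry data are access
restricted:

- contiguity graph: either a queen-adjacency grid or the 79-region
  near-square variant used by the registry preset;
- frailties drawn exactly from the sum-to-zero ICAR by component-wise
  eigendecomposition of the graph Laplacian (variance `tau2/lambda` along
  positive-eigenvalue directions, zero on the null space) — exact and
  cheap for up to a few hundred regions;
- event times `T = exp(mu + beta'x + W + rho*eps)` with the family's
  canonical error;
- categorical covariates drawn independently per patient from declared
  frequency mixes; the registry preset uses the published cohort's
  marginal frequencies (56.29% male, 85.49% ever-smoker, 51.99% good
  performance status, 45.14% stage IV, ...);
- right censoring is administrative by default: the cutoff is the
  empirical `(1 - target)` quantile of the simulated event times, which
  reproduces a target censoring fraction (the registry preset targets
  36.17%) to within sampling error.  A fixed cutoff time is available as
  the alternative mechanism.

Registry preset parameters chosen once as plausible for this disease
setting: `mu = 3.0` (reference-pattern median about 20 months),
`rho = 1.1`, `tau2 = 0.2` (frailty standard deviation about 0.35 on log
time), protective effects positive on log time (e.g. +0.25 female, +0.55
never-smoker) and advanced stage strongly negative (-1.9 for stage IV).

What the generator does **not** emulate: informative censoring,
within-region covariate clustering, time-varying covariates or competing
risks.  Passing tests therefore demonstrate correctness of the machinery
under the stated generative model, not robustness to those real-data
features.

## Derived-variable conventions

- Diagnostic delay: referral-to-diagnosis interval strictly greater than
  28 days; treatment delay: diagnosis-to-treatment strictly greater than
  42 days ("exceeds" read literally, so day 28/42 is timely); missing
  intervals become the explicit category `not_stated`.
- ECOG performance: score < 2 "good", >= 2 "poor", missing `not_stated`.
- Area socioeconomic score: quintiles over supplied regions, boundaries
  at the 20/40/60/80th percentiles, quintile 1 = least advantaged, ties
  broken by stable rank for determinism.
- "Not stated" is a modelled category wherever declared, never dropped;
  rows missing time or event are dropped with a logged count.
- Times are stored in months; day-valued inputs are converted with the
  mean Gregorian month (30.4375 days) on request.

## Numerical and design choices

- Tie conventions: deaths precede censorings at tied times (KM and
  risk-set construction); Breslow ties in the Cox partial likelihood.
- The Cox fit uses Newton-Raphson with step-halving; monotone likelihood
  is flagged at |beta| > 20.  The global proportional-hazards test is the
  score test of correlation between Schoenfeld residuals and transformed
  time (identity transform by default; log and rank exposed), using the
  averaged-information approximation.
- Percentages in descriptive tables are rounded half-up to two decimals,
  matching the published tables' formatting.
- Mortality-table chi-square is Pearson's without continuity correction.
- Test-suite problem sizes: recovery and selection experiments run on an
  8x10 queen grid with about 3,000 patients and scaled-down chains
  (burn-in 400-1000, 600-2000 monitored draws), sizes at which the
  posterior is informative while a full replicate set stays desk-scale.

## Known limitations

- The ICAR variance `tau2` mixes more slowly than the regression block;
  very short chains can understate it.  The scaled-down schedules used in
  the experiments were checked for coverage (16+/20 seeds).
- Criteria treat frailties as parameters; marginal (integrated-frailty)
  DIC/WAIC variants are out of scope.
- The sampler is single-CPU, dense-matrix; it is sized for hundreds of
  regions, not tens of thousands.
- Effect-direction labelling (`AHR`) is an AFT-based correspondence, not
  a semiparametric hazard-ratio estimate; for the log-logistic family it
  is exact on the event-odds scale, approximate on the hazard scale.
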