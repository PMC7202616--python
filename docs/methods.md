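# Methods

## Model and assumptions

All estimators target the same two-level linear mixed model. Subject *i*'s
outcome at occasion *j* is

    Y_ij = mu0 + mu_i + sum_k X_ijk * beta_ik + eps_ij

with `eps_ij ~ N(0, sigma2)` i.i.d., a random intercept deviation
`mu_i ~ N(0, tau2)` and, per non-reference condition *k*, a random treatment
effect `beta_ik ~ N(beta0_k, omega2_k)`. Random effects are mutually
independent (no intercept–slope correlation parameter) and independent of the
residuals. The model deliberately ignores time trends, carry-over between
conditions and residual autocorrelation: a condition's effect is assumed
constant in time and fully washed out before the next period, so only the
condition *label* matters, never its calendar position. For outcomes like body
weight this is a known misspecification, and it is the main caveat when
carrying conclusions from the simulation study to real self-measurement data.

Missing outcomes are retained in datasets (the occasion exists, the value does
not) and excluded from every likelihood and regression — complete-case per
observation, no imputation.

## Simulator and study conditions

`simulate_dataset` draws, per subject, `mu_i` and `beta_i`, then an equal
number *t* of control and treatment measurements whose within-subject order is
a uniformly random interleaving (a random permutation of the multiset of
condition labels — the minimal assumption when no block structure is imposed).
The default population parameters are mu0 = 0, tau2 = 1, beta0 = −2,
sigma2 = 1, and a between-subject treatment-effect SD of 0.5
(`omega2 = 0.25`), i.e. SD ratios of 1:1 (intercept : residual) and 0.5:1
(effect : residual). The scenario grid crosses n ∈ {20, 30, 40} subjects with
t ∈ {10, 20, 30} measurements *per condition* (a subject contributes 2t
observations); `t_is_total=True` selects the alternative reading in which t is
split across the two conditions. The full design uses 1000 replicates per
scenario; the shipped experiments run 200, which is enough to separate the
methods clearly, and because replicate RNG substreams are keyed by
`(seed, replicate_index)`, a scaled-down run is a prefix of the full one and
any single replicate can be regenerated in isolation.

## The three estimators

**IPD (two-step).** Per-subject OLS of outcome on the condition indicators
(equivalently condition-mean differences), residual variance with denominator
n − p (undefined for saturated fits), then a weighted aggregation with unit
weights by default (inverse-variance weights are available but are not the
default). The between-subject SDs are the weighted *sample SDs* of the
per-subject estimates. The two-step approach does not estimate the variance
components as model parameters, and the sample SD of noisy per-subject
estimates has expectation sqrt(omega2 + sampling variance) — the source of the
method's positive heterogeneity bias, which shrinks as t grows. Subjects
lacking a condition contribute to the intercept aggregation only; the fit
records how many subjects entered each effect.

**F-LME (maximum likelihood).** The marginal likelihood integrates the random
effects out: per subject, `V_i = sigma2*I + Z_i G Z_i'` with
`Z_i = [1 | indicators]` and `G = diag(tau2, omega2_k)`. Everything is reduced
to (K+1)-dimensional per-subject sufficient statistics through the Woodbury
identity (with the symmetric `I + G^{1/2} Z'Z G^{1/2}/sigma2` form, stable
when a variance sits at its floor), the fixed effects are profiled out by GLS,
and L-BFGS-B runs on the log-variances from three starts (IPD
method-of-moments, unit variances, tenth-scale variances) with relative
tolerance 1e-8 and a variance floor of 1e-10. ML is the default to match the
simulation experiment; REML is available (`reml=True`) with the usual caveat
that its variance estimates differ at small N. Per-subject predictions are
BLUPs, `E[theta_i | y_i]` at the fitted parameters, computed as
`beta + G Z' V^{-1}(y - Z beta)` so a floored variance component cleanly
yields complete shrinkage.

A note on shrinkage: the BLUP *aggregate* dispersion around the population
effect is always smaller than the per-subject OLS dispersion, and the tests
assert exactly that. The stronger subject-by-subject statement
|BLUP_i − beta0| ≤ |OLS_i − beta0| is *not* a theorem for the joint
intercept+slope model — the BLUP also loads on the subject's intercept
deviation (the subject means are correlated through mu_i), and in simulation
roughly 5% of subjects violate the pointwise inequality. The package therefore
documents and tests shrinkage as an aggregate property.

**B-LME (Gibbs).** Blocked Gibbs sampler in the centered parameterization
theta_i = (mu0 + mu_i, beta_i1, ..): (a) all subject coefficient vectors
jointly Normal given population parameters (vectorized stacked Cholesky);
(b) population coefficients, conditionally independent Normals given the
subject coefficients — drawn by inverse CDF from a uniform variate, so a
truncated full conditional (upper-bounded population effect) is sampled
exactly, without rejection loops, and the RNG stream is identical with and
without truncation; (c) variance components from inverse-gamma full
conditionals. Priors: Normal(mean, sd²) on each coefficient, default
inverse-gamma(0.001, 0.001) on each variance component (a conjugacy-motivated
choice the results are in principle sensitive to — it is surfaced in
`PriorSpec`, not hard-coded); "non-informative" is operationalized as
Normal(0, 10⁶) coefficients plus those variance defaults, diffuse enough that
posterior means match the ML fit within Monte-Carlo error. Defaults: 4 chains,
1000 warmup + 1000 retained draws, thinning 1, an explicit seed required.
Diagnostics (split-R̂, ESS, MCSE) come from arviz; R̂ > 1.05 on a population
parameter sets a warning flag without failing the fit. A truncated population
prior bounds only beta0_k: individual effects are never truncated. Subject
draws are consumed in dataset order, so relabeling subjects permutes the
stream; population posteriors agree under relabeling up to Monte-Carlo error
(tested at 3×MCSE), not bitwise. For validation, variance components can be
pinned (`fixed_variances=`), making the coefficient posterior available in
closed form (GLS).

## Evaluation design

`run_scenario` simulates each replicate once and fits every requested method
on the same dataset (paired design). The accuracy measure is the RMSE of the
per-subject effect predictions against the recorded truth, computed *within*
a replicate over its subjects, so the experiment yields one RMSE per
replicate per method — the reading under which "the distribution of RMSE
values over replications" is well defined. Replicates where any method fails
are excluded for all methods (pairwise exclusion) and counted, never imputed.
B-LME joins grids at reduced MCMC settings by default (2 chains, 400+400)
because full-length chains across hundreds of replicates are a long-running
mode, not a default.

## Empirical pipeline

The 3-condition weight-study analysis extends the model to two indicator
variables (each treatment period vs baseline), each with its own independent
random effect. Weeks map to days as 9 weeks × 7 daily measurements = 63
slots: days 1–21 baseline, 22–42 snack reduction, 43–63 activity increase,
with the two treatment blocks exchanged for swapped-order subjects. The two
priors compared are Normal(−1, 5²) kg on both treatment effects ("weak") and
the same distribution truncated above at 0 ("negative") — identical for the
two conditions, expressing no a-priori difference between them. Weekly
summaries use 7-observation windows.

The fixture generator is *synthetic*: it reproduces the design's shape
(12 subjects, 63 daily slots, 2 swapped subjects, per-subject missing-day
counts realized exactly, max 41 of 63) with baseline weights Normal(75, 8²) kg,
mean effects −1 and −1.5 kg with ~1 kg heterogeneity, and 0.7 kg day-to-day
noise — values chosen once as realistic for daily self-weighing. It
deliberately omits features of the real data the model also ignores: gradual
(rather than instantaneous) weight change, carry-over between periods, and
any informative missingness (days are dropped uniformly at random). Passing
the pipeline's tests therefore demonstrates the machinery and the
prior-sensitivity contracts, not robustness to those violations.

## Numerical choices and degenerate inputs

- Variance floor 1e-10 (ML) keeps every V_i positive definite; noiseless data
  drive variance estimates to the floor while the coefficient estimates stay
  exact.
- Truncated-normal inverse-CDF draws clip the uniform argument to
  [1e-300, 1−1e-16] and the result to the bound, so extreme bound/mean
  configurations cannot produce infinities.
- CSV round trips are lossless: outcomes are written with shortest-unique
  float formatting and parsed with correctly-rounded `float()`.
- Saturated per-subject fits (zero residual df) have undefined residual
  variance and are skipped in the IPD residual-variance mean; a subject with
  no observed reference condition has no estimable effect and is excluded
  from effect aggregation (documented in the fit's diagnostics).
- Ties/order: subjects are processed in first-appearance order everywhere;
  the ML likelihood is invariant to relabeling and reordering (tested).

## Known limitations

- No time trends, carry-over, autocorrelation, covariates, or imputation —
  by design, matching the simulation experiment's scope.
- IPD aggregation is the simple (weighted) mean; random-effects
  meta-analytic variance estimators (DerSimonian–Laird etc.) are out of scope.
- The Gibbs sampler is not adaptive; for very small heterogeneity the
  inverse-gamma(0.001, 0.001) prior can matter, and users with strong views
  should set `variance_shape`/`variance_scale` explicitly.
- How the two-step method's heterogeneity SD "estimate" should be defined is
  itself a modelling choice (no variance parameter exists in that procedure);
  the sample-SD convention used here is what produces its documented positive
  bias.
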