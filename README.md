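# nof1sim

Simulation and analysis of **N-of-1 trials** — single-subject crossover
experiments in which each participant alternates between a control and one or
more treatment conditions while repeatedly measuring a continuous outcome
(daily body weight, symptom scores, ...). Multi-subject N-of-1 studies promise
both a population-level effect estimate and *personalized* effect estimates,
which makes the choice of statistical method consequential. This package is
for biostatisticians and quantitative nutrition/health researchers who want to
compare those methods on data with known ground truth, or apply them to their
own self-measurement studies.

## The model

For subject *i* = 1..N at occasion *j* = 1..J<sub>i</sub>:

```
Y_ij = mu0 + mu_i + X_ij * beta_i + eps_ij
eps_ij ~ N(0, sigma^2)
mu_i   ~ N(0, tau^2)
beta_i ~ N(beta0, omega^2)
```

with X<sub>ij</sub> the 0/1 treatment indicator (one indicator per treatment
condition in multi-condition designs), mu0 the population baseline, beta0 the
average treatment effect, and independent random intercepts and random
treatment effects capturing between-subject heterogeneity.

Three estimators of this model are implemented:

- **IPD** (`fit_ipd`) — two-step individual-participant-data meta-analysis:
  per-subject OLS, then a unit-weighted mean of the subject estimates. The
  between-subject SD is the sample SD of the per-subject estimates, which is
  *positively biased* because each estimate carries its own sampling error.
- **F-LME** (`fit_lme_ml`) — one-step frequentist mixed model, maximum
  likelihood via a profiled, Woodbury-reduced marginal likelihood with
  multi-start quasi-Newton optimization; per-subject effects are
  empirical-Bayes (BLUP) predictions.
- **B-LME** (`fit_lme_bayes`) — the same model with a blocked Gibbs sampler;
  supports informative Normal priors on the population effects, optionally
  truncated (e.g. upper limit 0 to encode "the average subject does not gain
  weight"). With a diffuse prior it reproduces the ML answer.

`run_scenario`/`run_grid` compare the estimators by the per-replicate RMSE of
the per-subject effect predictions against the simulated truth, and
`analyze_empirical` reproduces a weak-vs-truncated-prior analysis of a
3-condition self-measurement weight study (a synthetic fixture generator with
the study's exact shape — 12 subjects, 63 daily measurements, swapped
condition orders, realistic missingness — is included).

## Worked example

```python
import nof1sim as n

scenario = n.ScenarioSpec(n_subjects=20, t_per_condition=10, seed=1)
dataset, truth = n.simulate_dataset(scenario, replicate_index=0)

ipd = n.fit_ipd(dataset)
flme = n.fit_lme_ml(dataset)
post, blme = n.fit_lme_bayes(dataset, prior=n.PriorSpec.noninformative(),
                             chains=4, warmup=1000, draws=1000, seed=1)

print(f"IPD   : beta0 = {ipd.effect():+.3f}  omega = {ipd.omega['treatment']:.3f}")
print(f"F-LME : beta0 = {flme.effect():+.3f}  omega = {flme.omega['treatment']:.3f}")
print(f"B-LME : beta0 = {blme.effect():+.3f}  omega = {blme.omega['treatment']:.3f}")

true_beta = [t.beta_i for t in truth]
for name, fit in (("IPD", ipd), ("F-LME", flme)):
    est = [fit.subject_effects["treatment"][t.subject_id] for t in truth]
    print(f"RMSE(beta_i) {name:6s}: {n.rmse(est, true_beta):.3f}")
```

prints

```
IPD   : beta0 = -1.967  omega = 0.682
F-LME : beta0 = -1.967  omega = 0.520
B-LME : beta0 = -1.965  omega = 0.544
RMSE(beta_i) IPD   : 0.408
RMSE(beta_i) F-LME : 0.311
```

The generating values were beta0 = −2 and omega = 0.5. All three methods agree
on the population effect (with balanced data the two-step mean equals the
one-step estimate), but the two-step IPD overstates the between-subject SD
(0.682 vs 0.5) while the mixed models sit close to it, and the mixed model's
shrunken per-subject predictions are ~25% more accurate (RMSE 0.311 vs 0.408).

The same operations are available from the shell:

```sh
nof1 simulate -c scenario.yaml -o out/           # dataset.csv + truth.csv
nof1 benchmark -c grid.yaml -o bench/            # tidy RMSE summaries
nof1 fit --data out/dataset.csv --method flme -o fit/
nof1 empirical --fixture --seed 4 -o report/     # weak vs truncated priors
```

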