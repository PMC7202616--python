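"""Bayesian linear mixed model for N-of-1 trials via blocked Gibbs sampling.

Same hierarchical model as the frequentist fit, estimated by MCMC so that
prior knowledge about the population treatment effect can be included.
The sampler cycles through conjugate full conditionals:

(a) per-subject coefficients ``theta_i = (mu0 + mu_i, beta_i1, ...,
    beta_iK)``, jointly Normal given the population parameters;
(b) population coefficients ``(mu0, beta0_k)``, independent Normals given
    the subject coefficients and variances — a *truncated* Normal,
    sampled exactly by inverse-CDF, when an effect prior carries an upper
    bound (e.g. "the population cannot gain weight": upper limit 0);
(c) variance components ``tau2, omega2_k, sigma2`` from inverse-gamma
    full conditionals.

A truncated population prior bounds only the population mean effect;
individual effects remain free to take either sign.  With a sufficiently
diffuse ("non-informative") prior the posterior means numerically
reproduce the maximum-likelihood fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .lme_freq import SubjectStats, _check_identifiable, subject_stats
from .results import FitResult
from .trial_data import TrialDataset, design_matrix

__all__ = ["PriorSpec", "PosteriorSummary", "fit_lme_bayes", "compare_priors"]


def _per_condition(value, conditions: list[str]) -> dict:
    if isinstance(value, dict):
        return {c: value.get(c) for c in conditions}
    return {c: value for c in conditions}


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the population-level parameters.

    Effect priors are Normal(mean, sd^2), optionally truncated above at
    ``effect_upper`` (scalars apply to every non-reference condition;
    dicts set them per condition).  Variance components get
    inverse-gamma(shape, scale) priors, weakly informative by default.
    ``non_informative=True`` overrides the coefficient priors with
    Normal(0, 1e6) and removes any truncation.
    """

    effect_mean: float | dict = 0.0
    effect_sd: float | dict = 1000.0
    effect_upper: float | dict | None = None
    intercept_mean: float = 0.0
    intercept_sd: float = 1000.0
    variance_shape: float = 0.001
    variance_scale: float = 0.001
    non_informative: bool = False

    def __post_init__(self) -> None:
        sds = self.effect_sd.values() if isinstance(self.effect_sd, dict) else [self.effect_sd]
        if any(s is not None and s <= 0 for s in sds) or self.intercept_sd <= 0:
            raise ValueError("prior SDs must be > 0")
        uppers = (
            self.effect_upper.values()
            if isinstance(self.effect_upper, dict)
            else [self.effect_upper]
        )
        if any(u is not None and not np.isfinite(u) for u in uppers):
            raise ValueError("truncation bound must be finite")

    @classmethod
    def noninformative(cls) -> "PriorSpec":
        return cls(non_informative=True)

    @classmethod
    def weak(cls, mean: float = -1.0, sd: float = 5.0) -> "PriorSpec":
        """Weakly informative effect prior (default: -1 kg mean, 5 kg SD)."""
        return cls(effect_mean=mean, effect_sd=sd)

    @classmethod
    def truncated(cls, mean: float = -1.0, sd: float = 5.0, upper: float = 0.0) -> "PriorSpec":
        """Same Normal as :meth:`weak` but truncated above (default at 0)."""
        return cls(effect_mean=mean, effect_sd=sd, effect_upper=upper)

    def resolve(self, conditions: list[str]):
        """(means, sds, uppers) for [intercept] + effect coefficients."""
        if self.non_informative:
            k = len(conditions)
            return np.zeros(k + 1), np.full(k + 1, 1000.0), [None] * (k + 1)
        means = _per_condition(self.effect_mean, conditions)
        sds = _per_condition(self.effect_sd, conditions)
        ups = _per_condition(self.effect_upper, conditions)
        m = np.array([self.intercept_mean] + [means[c] for c in conditions], dtype=float)
        s = np.array([self.intercept_sd] + [sds[c] for c in conditions], dtype=float)
        u = [None] + [ups[c] for c in conditions]
        return m, s, u


@dataclass
class PosteriorSummary:
    """Retained MCMC draws plus convenience summaries.

    ``draws`` maps parameter names (``mu0``, ``beta0[cond]``, ``tau2``,
    ``omega2[cond]``, ``sigma2``, ``intercept[sid]``, ``beta[sid,cond]``)
    to arrays of shape ``(chains, draws)``.  Subject-level parameters are
    on the absolute scale.
    """

    draws: dict[str, np.ndarray]
    settings: dict

    def mean(self, name: str) -> float:
        return float(self.draws[name].mean())

    def sd(self, name: str) -> float:
        return float(self.draws[name].std(ddof=1))

    def mcse(self, name: str) -> float:
        import arviz as az

        ess = float(az.ess(self.draws[name]))
        return self.sd(name) / np.sqrt(max(ess, 1.0))

    def summary(self) -> pd.DataFrame:
        import arviz as az

        rows = []
        for name, arr in self.draws.items():
            flat = arr.ravel()
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "q2.5": np.quantile(flat, 0.025),
                    "q97.5": np.quantile(flat, 0.975),
                    "rhat": float(az.rhat(arr)),
                    "ess": float(az.ess(arr)),
                }
            )
        return pd.DataFrame(rows)

    def draws_frame(self) -> pd.DataFrame:
        """Wide table: one row per (chain, draw), one column per parameter."""
        chains, ndraw = next(iter(self.draws.values())).shape
        cols = {
            "chain": np.repeat(np.arange(chains), ndraw),
            "draw": np.tile(np.arange(ndraw), chains),
        }
        cols.update({name: arr.ravel() for name, arr in self.draws.items()})
        return pd.DataFrame(cols)


def _truncnorm_draw(u: float, mean: float, sd: float, upper: float | None) -> float:
    """Inverse-CDF draw from Normal(mean, sd^2), optionally upper-truncated.

    Exact (no rejection loop); ``u`` is a uniform(0,1) variate so the RNG
    stream is consumed identically whether or not a bound is present.
    """
    if upper is None:
        p = u
    else:
        p = u * max(ndtr((upper - mean) / sd), 1e-300)
    x = mean + sd * ndtri(np.clip(p, 1e-300, 1.0 - 1e-16))
    if upper is not None:
        x = min(x, upper)
    return float(x)


def _inv_gamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    return float(scale / rng.gamma(shape))


def _run_chain(
    stats: SubjectStats,
    prior_m: np.ndarray,
    prior_s: np.ndarray,
    prior_upper: list,
    a0: float,
    b0: float,
    warmup: int,
    n_draws: int,
    thin: int,
    rng: np.random.Generator,
    fixed_variances: np.ndarray | None,
    fixed_sigma2: float | None,
):
    N, p = stats.u.shape
    n_total = stats.n_total
    eye = np.eye(p)

    # dispersed, data-anchored initial values
    ybar = stats.u[:, 0].sum() / n_total
    b = np.array([ybar] + [0.0] * (p - 1)) + rng.normal(0.0, 1.0, size=p)
    for k in range(1, p):
        if prior_upper[k] is not None:
            b[k] = min(b[k], prior_upper[k] - 0.1)
    variances = (
        fixed_variances.copy()
        if fixed_variances is not None
        else np.exp(rng.normal(0.0, 0.5, size=p))
    )
    sigma2 = fixed_sigma2 if fixed_sigma2 is not None else float(np.exp(rng.normal(0.0, 0.5)))
    theta = b + rng.normal(0.0, 0.1, size=(N, p))

    kept_theta = np.empty((n_draws, N, p))
    kept_b = np.empty((n_draws, p))
    kept_var = np.empty((n_draws, p))
    kept_sigma2 = np.empty(n_draws)

    total = warmup + n_draws * thin
    for it in range(total):
        # (a) subject coefficients: Normal(P^-1 rhs, P^-1)
        P = stats.S / sigma2 + eye / variances
        rhs = stats.u / sigma2 + b / variances
        L = np.linalg.cholesky(P)
        mean = np.linalg.solve(P, rhs[:, :, None])[:, :, 0]
        z = rng.standard_normal((N, p))
        theta = mean + np.linalg.solve(
            np.transpose(L, (0, 2, 1)), z[:, :, None]
        )[:, :, 0]

        # (b) population coefficients, conditionally independent given theta
        u_coef = rng.uniform(size=p)
        for j in range(p):
            prec = N / variances[j] + 1.0 / prior_s[j] ** 2
            m = (theta[:, j].sum() / variances[j] + prior_m[j] / prior_s[j] ** 2) / prec
            b[j] = _truncnorm_draw(u_coef[j], m, np.sqrt(1.0 / prec), prior_upper[j])

        # (c) variance components
        if fixed_variances is None:
            dev2 = ((theta - b) ** 2).sum(axis=0)
            for j in range(p):
                variances[j] = _inv_gamma(rng, a0 + N / 2.0, b0 + dev2[j] / 2.0)
        if fixed_sigma2 is None:
            rss = float(
                np.sum(stats.q)
                - 2.0 * np.einsum("np,np->", theta, stats.u)
                + np.einsum("np,npq,nq->", theta, stats.S, theta)
            )
            sigma2 = _inv_gamma(rng, a0 + n_total / 2.0, b0 + max(rss, 0.0) / 2.0)

        if it >= warmup and (it - warmup) % thin == 0:
            d = (it - warmup) // thin
            kept_theta[d] = theta
            kept_b[d] = b
            kept_var[d] = variances
            kept_sigma2[d] = sigma2

    return kept_b, kept_var, kept_sigma2, kept_theta


def fit_lme_bayes(
    dataset: TrialDataset,
    prior: PriorSpec | None = None,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    thin: int = 1,
    seed: int | None = None,
    fixed_variances: dict | None = None,
) -> tuple[PosteriorSummary, FitResult]:
    """Sample the posterior of the mixed model under the given priors.

    ``seed`` is required — there is no silent default seeding.  Chains
    start from dispersed, data-anchored values on independent substreams
    of the seed.  ``fixed_variances`` (keys among ``tau2``, ``omega2``,
    ``sigma2``) pins variance components instead of sampling them, which
    makes the coefficient posterior available in closed form for
    validation.

    Returns the posterior draws/diagnostics and a :class:`FitResult`
    filled from posterior means (SDs are square roots of the posterior
    mean variances; per-subject effects are posterior means of the
    subject coefficients).
    """
    if seed is None:
        raise ValueError("fit_lme_bayes requires an explicit seed")
    prior = prior or PriorSpec.noninformative()
    dm = design_matrix(dataset)
    stats = subject_stats(dm)
    _check_identifiable(stats)
    nonref = stats.condition_labels
    p = stats.p
    prior_m, prior_s, prior_upper = prior.resolve(nonref)

    fv = None
    fs2 = None
    if fixed_variances:
        fv = np.array(
            [fixed_variances.get("tau2", np.nan)]
            + [
                fixed_variances.get("omega2", np.nan)
                if not isinstance(fixed_variances.get("omega2"), dict)
                else fixed_variances["omega2"][c]
                for c in nonref
            ]
        )
        if np.isnan(fv).any():
            raise ValueError("fixed_variances must pin tau2 and omega2 together")
        fs2 = fixed_variances.get("sigma2")
        if fs2 is None:
            raise ValueError("fixed_variances must include sigma2")

    per_chain = []
    for c in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), c]))
        per_chain.append(
            _run_chain(
                stats, prior_m, prior_s, prior_upper,
                prior.variance_shape, prior.variance_scale,
                warmup, draws, thin, rng, fv, fs2,
            )
        )

    b_arr = np.stack([pc[0] for pc in per_chain])        # (chains, draws, p)
    var_arr = np.stack([pc[1] for pc in per_chain])      # (chains, draws, p)
    s2_arr = np.stack([pc[2] for pc in per_chain])       # (chains, draws)
    theta_arr = np.stack([pc[3] for pc in per_chain])    # (chains, draws, N, p)

    out: dict[str, np.ndarray] = {"mu0": b_arr[:, :, 0]}
    for k, cond in enumerate(nonref):
        out[f"beta0[{cond}]"] = b_arr[:, :, k + 1]
    out["tau2"] = var_arr[:, :, 0]
    for k, cond in enumerate(nonref):
        out[f"omega2[{cond}]"] = var_arr[:, :, k + 1]
    out["sigma2"] = s2_arr
    for i, sid in enumerate(stats.subjects):
        out[f"intercept[{sid}]"] = theta_arr[:, :, i, 0]
        for k, cond in enumerate(nonref):
            out[f"beta[{sid},{cond}]"] = theta_arr[:, :, i, k + 1]

    settings = {
        "chains": chains, "warmup": warmup, "draws": draws, "thin": thin,
        "seed": seed, "prior": prior,
    }
    post = PosteriorSummary(draws=out, settings=settings)

    import arviz as az

    pop_names = ["mu0", "tau2", "sigma2"] + [f"beta0[{c}]" for c in nonref] + [
        f"omega2[{c}]" for c in nonref
    ]
    if fixed_variances:
        pop_names = [n for n in pop_names if n not in ("tau2", "sigma2")
                     and not n.startswith("omega2")]
    rhats = {n: float(az.rhat(out[n])) for n in pop_names} if chains > 1 else {}
    rhat_warning = any(r > 1.05 for r in rhats.values())

    fit = FitResult(
        method="lme_bayes",
        mu0=post.mean("mu0"),
        beta0={c: post.mean(f"beta0[{c}]") for c in nonref},
        tau=float(np.sqrt(post.mean("tau2"))),
        omega={c: float(np.sqrt(post.mean(f"omega2[{c}]"))) for c in nonref},
        sigma=float(np.sqrt(post.mean("sigma2"))),
        subject_intercepts={s: post.mean(f"intercept[{s}]") for s in stats.subjects},
        subject_effects={
            c: {s: post.mean(f"beta[{s},{c}]") for s in stats.subjects} for c in nonref
        },
        converged=not rhat_warning,
        n_iter=chains * (warmup + draws * thin),
        diagnostics={"rhat": rhats, "rhat_warning": rhat_warning,
                     "n_draws_retained": chains * draws},
    )
    return post, fit


@dataclass
class PriorComparison:
    """Paired results of the same model under several priors."""

    population: pd.DataFrame
    subjects: pd.DataFrame
    fits: dict[str, FitResult]
    posteriors: dict[str, PosteriorSummary]


def compare_priors(
    dataset: TrialDataset,
    priors: dict[str, PriorSpec],
    seed: int | None = None,
    **mcmc,
) -> PriorComparison:
    """Fit once per prior under identical MCMC settings and seed.

    Returns paired population and per-subject summary tables so the
    influence of the prior can be read off row by row.
    """
    if len(priors) < 2:
        raise ValueError("need at least 2 priors to compare")
    fits: dict[str, FitResult] = {}
    posteriors: dict[str, PosteriorSummary] = {}
    pop_rows = []
    subj_rows = []
    for name, prior in priors.items():
        post, fit = fit_lme_bayes(dataset, prior=prior, seed=seed, **mcmc)
        fits[name] = fit
        posteriors[name] = post
        for cond, val in fit.beta0.items():
            arr = post.draws[f"beta0[{cond}]"].ravel()
            pop_rows.append(
                {
                    "prior": name, "condition": cond, "mean": val,
                    "sd": arr.std(ddof=1),
                    "q2.5": np.quantile(arr, 0.025),
                    "q97.5": np.quantile(arr, 0.975),
                }
            )
        for cond, per_subject in fit.subject_effects.items():
            for sid, val in per_subject.items():
                arr = post.draws[f"beta[{sid},{cond}]"].ravel()
                subj_rows.append(
                    {
                        "prior": name, "subject": sid, "condition": cond,
                        "mean": val, "sd": arr.std(ddof=1),
                        "q2.5": np.quantile(arr, 0.025),
                        "q97.5": np.quantile(arr, 0.975),
                    }
                )
    return PriorComparison(
        population=pd.DataFrame(pop_rows),
        subjects=pd.DataFrame(subj_rows),
        fits=fits,
        posteriors=posteriors,
    )
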