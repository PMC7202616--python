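"""Frequentist linear mixed model for N-of-1 trials (maximum likelihood).

The model has fixed effects (mu0, beta0_k) and, per subject, a random
intercept with variance tau2 and one random effect per non-reference
condition with variance omega2_k, all mutually independent.  Integrating
the random effects out, subject i's outcomes are jointly Normal with mean
``Z_i b`` and covariance::

    V_i = sigma2 * I + Z_i G Z_i',   G = diag(tau2, omega2_1, ..., omega2_K)

where ``Z_i = [1 | indicator columns]`` serves as both the fixed- and the
random-effect design.  The marginal likelihood is maximized by profiling
the fixed effects (GLS at the current variances) and running a
quasi-Newton search over the log-variances from three starting points.
All per-subject quantities reduce to small (K+1)-dimensional sufficient
statistics via the Woodbury identity, so a fit costs milliseconds even at
thousands of observations.

Per-subject treatment effects are empirical-Bayes (BLUP) predictions:
the conditional mean of the subject's coefficients given their data at
the fitted population parameters, which shrinks each subject toward the
population mean by an amount governed by the variance ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .ipd import EstimationError, fit_ipd
from .results import FitResult
from .trial_data import DesignMatrix, TrialDataset, design_matrix

__all__ = ["fit_lme_ml", "predict_subject_effects", "VARIANCE_FLOOR"]

VARIANCE_FLOOR = 1e-10  # keeps every V_i positive definite
_LOG_FLOOR = np.log(VARIANCE_FLOOR)


@dataclass(frozen=True)
class SubjectStats:
    """Per-subject sufficient statistics S=Z'Z, u=Z'y, q=y'y, n."""

    S: np.ndarray  # (N, p, p)
    u: np.ndarray  # (N, p)
    q: np.ndarray  # (N,)
    n: np.ndarray  # (N,)
    subjects: list[str]
    condition_labels: list[str]

    @property
    def p(self) -> int:
        return self.S.shape[1]

    @property
    def n_total(self) -> int:
        return int(self.n.sum())


def subject_stats(dm: DesignMatrix) -> SubjectStats:
    """Collapse a design matrix into per-subject sufficient statistics."""
    Z = np.column_stack([np.ones(dm.n_obs), dm.X])
    N = len(dm.subjects)
    p = Z.shape[1]
    S = np.zeros((N, p, p))
    u = np.zeros((N, p))
    q = np.zeros(N)
    n = np.zeros(N, dtype=int)
    for i in range(N):
        rows = dm.subject_index == i
        Zi, yi = Z[rows], dm.y[rows]
        S[i] = Zi.T @ Zi
        u[i] = Zi.T @ yi
        q[i] = yi @ yi
        n[i] = rows.sum()
    return SubjectStats(S=S, u=u, q=q, n=n, subjects=list(dm.subjects),
                        condition_labels=list(dm.condition_labels))


def _gls_pieces(stats: SubjectStats, variances: np.ndarray, sigma2: float):
    """Woodbury-reduced GLS ingredients at fixed variance components.

    Returns (A, b, c, logdetV) with A = sum Z'V^-1 Z, b = sum Z'V^-1 y,
    c = sum y'V^-1 y and logdetV = sum log|V_i|.
    """
    g = np.sqrt(variances)  # (p,)
    W = np.eye(stats.p) + (g[:, None] * stats.S * g[None, :]) / sigma2
    Winv = np.linalg.inv(W)
    sign, logdetW = np.linalg.slogdet(W)
    C = (g[:, None] * Winv * g[None, :]) / sigma2  # (N, p, p)
    SC = stats.S @ C
    A_i = (stats.S - SC @ stats.S) / sigma2
    b_i = (stats.u - np.einsum("npq,nq->np", SC, stats.u)) / sigma2
    Cu = np.einsum("npq,nq->np", C, stats.u)
    c_i = (stats.q - np.einsum("np,np->n", stats.u, Cu)) / sigma2
    logdetV = float(np.sum(stats.n * np.log(sigma2) + logdetW))
    return A_i.sum(axis=0), b_i.sum(axis=0), float(c_i.sum()), logdetV


def _neg_loglik(log_var: np.ndarray, stats: SubjectStats, reml: bool) -> float:
    var = np.exp(np.clip(log_var, _LOG_FLOOR, 50.0))
    variances, sigma2 = var[:-1], var[-1]
    A, b, c, logdetV = _gls_pieces(stats, variances, sigma2)
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return 1e12
    quad = c - beta @ b
    nll = 0.5 * (logdetV + quad + stats.n_total * np.log(2.0 * np.pi))
    if reml:
        sign, logdetA = np.linalg.slogdet(A)
        nll += 0.5 * logdetA
    if not np.isfinite(nll):
        return 1e12
    return nll


def _blups(stats: SubjectStats, beta: np.ndarray, variances: np.ndarray,
           sigma2: float) -> np.ndarray:
    """Conditional means of per-subject coefficients (absolute scale).

    theta_i = beta + G Z' V^-1 (y_i - Z_i beta); the form with G outside
    the inverse is stable when a variance sits at the floor.
    """
    g = np.sqrt(variances)
    W = np.eye(stats.p) + (g[:, None] * stats.S * g[None, :]) / sigma2
    Winv = np.linalg.inv(W)
    C = (g[:, None] * Winv * g[None, :]) / sigma2
    r = stats.u - stats.S @ beta  # Z'(y - Z beta)
    ZtVinv_r = (r - np.einsum("npq,nq->np", stats.S @ C, r)) / sigma2
    return beta[None, :] + variances[None, :] * ZtVinv_r


def _check_identifiable(stats: SubjectStats) -> None:
    if len(stats.subjects) < 2:
        raise EstimationError("need >= 2 subjects with data")
    # column k+1 of S's diagonal counts the subject's obs in condition k
    for k, cond in enumerate(stats.condition_labels):
        n_with = int(np.sum(stats.S[:, k + 1, k + 1] > 0))
        if n_with < 2:
            raise EstimationError(f"condition {cond}: observed in < 2 subjects")
    n_ref = int(np.sum(stats.n - stats.S[:, 1:, 1:].diagonal(axis1=1, axis2=2).sum(axis=1) > 0))
    if n_ref < 2:
        raise EstimationError("reference condition observed in < 2 subjects")


def _starts(dataset: TrialDataset, p: int) -> list[np.ndarray]:
    """Three optimizer starts: IPD moments, unit variances, tenth-scale."""
    starts = [np.zeros(p + 1), np.full(p + 1, np.log(0.1))]
    try:
        ipd = fit_ipd(dataset)
        mom = np.empty(p + 1)
        mom[0] = max(ipd.tau**2, 1e-4)
        for k, cond in enumerate(dataset.conditions[1:]):
            mom[k + 1] = max(ipd.omega.get(cond, 1.0) ** 2, 1e-4)
        mom[-1] = max(ipd.sigma**2, 1e-4) if np.isfinite(ipd.sigma) else 1.0
        starts.insert(0, np.log(mom))
    except (EstimationError, ValueError):
        pass
    return starts


def fit_lme_ml(dataset: TrialDataset, reml: bool = False,
               ftol: float = 1e-8) -> FitResult:
    """Fit the mixed model by (restricted) maximum likelihood.

    Returns population estimates, BLUP per-subject predictions and
    optimizer diagnostics.  ``reml=True`` switches to the restricted
    likelihood, whose variance estimates differ at small N (ML divides by
    N where REML divides by N minus the fixed-effect count).
    """
    dm = design_matrix(dataset)
    stats = subject_stats(dm)
    _check_identifiable(stats)
    p = stats.p

    best = None
    total_iters = 0
    for x0 in _starts(dataset, p):
        res = minimize(
            _neg_loglik, x0, args=(stats, reml), method="L-BFGS-B",
            bounds=[(_LOG_FLOOR, 50.0)] * (p + 1),
            options={"ftol": ftol, "gtol": 1e-8, "maxiter": 500},
        )
        total_iters += res.nit
        if best is None or res.fun < best.fun:
            best = res

    var = np.exp(np.clip(best.x, _LOG_FLOOR, 50.0))
    variances, sigma2 = var[:-1], float(var[-1])
    A, b, _, _ = _gls_pieces(stats, variances, sigma2)
    beta = np.linalg.solve(A, b)
    theta = _blups(stats, beta, variances, sigma2)

    nonref = stats.condition_labels
    return FitResult(
        method="lme_reml" if reml else "lme_ml",
        mu0=float(beta[0]),
        beta0={c: float(beta[k + 1]) for k, c in enumerate(nonref)},
        tau=float(np.sqrt(variances[0])),
        omega={c: float(np.sqrt(variances[k + 1])) for k, c in enumerate(nonref)},
        sigma=float(np.sqrt(sigma2)),
        subject_intercepts={s: float(theta[i, 0]) for i, s in enumerate(stats.subjects)},
        subject_effects={
            c: {s: float(theta[i, k + 1]) for i, s in enumerate(stats.subjects)}
            for k, c in enumerate(nonref)
        },
        converged=bool(best.success),
        n_iter=total_iters,
        diagnostics={"loglik": -float(best.fun), "optimizer": best.message,
                     "n_obs": stats.n_total},
    )


def predict_subject_effects(dataset: TrialDataset, fit: FitResult):
    """Empirical-Bayes per-subject predictions at given population values.

    Recomputes the BLUPs from any :class:`FitResult` carrying finite
    population parameters (they need not come from :func:`fit_lme_ml`),
    so the shrinkage implied by an external parameter choice can be
    inspected.  Returns ``(intercepts, effects)`` dicts on the absolute
    scale.
    """
    dm = design_matrix(dataset)
    stats = subject_stats(dm)
    nonref = stats.condition_labels
    beta = np.array([fit.mu0] + [fit.beta0[c] for c in nonref])
    variances = np.array(
        [max(fit.tau**2, VARIANCE_FLOOR)]
        + [max(fit.omega[c] ** 2, VARIANCE_FLOOR) for c in nonref]
    )
    sigma2 = max(fit.sigma**2, VARIANCE_FLOOR)
    theta = _blups(stats, beta, variances, sigma2)
    intercepts = {s: float(theta[i, 0]) for i, s in enumerate(stats.subjects)}
    effects = {
        c: {s: float(theta[i, k + 1]) for i, s in enumerate(stats.subjects)}
        for k, c in enumerate(nonref)
    }
    return intercepts, effects
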