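"""Independent dense-matrix oracles used to validate the estimators.

Everything here works directly on full per-subject covariance matrices
(sigma2*I + Z G Z') with plain numpy/scipy linear algebra — deliberately
avoiding the package's Woodbury-reduced likelihood code so the two
routes stay independent.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.stats import multivariate_normal


def _subject_blocks(dataset):
    """(Z_i, y_i) per subject from the raw frame, missing rows dropped."""
    nonref = list(dataset.conditions[1:])
    blocks = []
    for sid in dataset.subjects:
        sub = dataset.subject_frame(sid).dropna(subset=["outcome"]).sort_values("time")
        if len(sub) == 0:
            continue
        Z = np.column_stack(
            [np.ones(len(sub))]
            + [(sub["condition"] == c).to_numpy(dtype=float) for c in nonref]
        )
        blocks.append((Z, sub["outcome"].to_numpy(dtype=float)))
    return blocks


def dense_profile_loglik(dataset, tau2, omega2, sigma2) -> float:
    """Marginal log-likelihood at given variances, fixed effects profiled
    out by dense GLS."""
    blocks = _subject_blocks(dataset)
    p = blocks[0][0].shape[1]
    G = np.diag([tau2] + [omega2] * (p - 1))
    A = np.zeros((p, p))
    b = np.zeros(p)
    Vs = []
    for Z, y in blocks:
        V = sigma2 * np.eye(len(y)) + Z @ G @ Z.T
        Vi = np.linalg.inv(V)
        A += Z.T @ Vi @ Z
        b += Z.T @ Vi @ y
        Vs.append((Z, y, V))
    beta = np.linalg.solve(A, b)
    ll = 0.0
    for Z, y, V in Vs:
        ll += multivariate_normal.logpdf(y, mean=Z @ beta, cov=V)
    return float(ll)


def brute_force_max_loglik(dataset) -> float:
    """Maximize the marginal likelihood by dense grid search plus polish."""
    grid = np.log([0.01, 0.05, 0.2, 0.5, 1.0, 2.0, 5.0])

    def nll(logv):
        v = np.exp(np.clip(logv, -25, 25))
        try:
            return -dense_profile_loglik(dataset, v[0], v[1], v[2])
        except np.linalg.LinAlgError:
            return 1e12

    best_x, best_f = None, np.inf
    for combo in itertools.product(grid, repeat=3):
        f = nll(np.array(combo))
        if f < best_f:
            best_f, best_x = f, np.array(combo)
    res = minimize(nll, best_x, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return -float(res.fun)


def gls_posterior(dataset, tau2, omega2, sigma2):
    """Flat-prior posterior (mean, cov) of the fixed effects at fixed
    variances — the exact coefficient posterior the Gibbs sampler should
    reproduce."""
    blocks = _subject_blocks(dataset)
    p = blocks[0][0].shape[1]
    G = np.diag([tau2] + [omega2] * (p - 1))
    A = np.zeros((p, p))
    b = np.zeros(p)
    for Z, y in blocks:
        Vi = np.linalg.inv(sigma2 * np.eye(len(y)) + Z @ G @ Z.T)
        A += Z.T @ Vi @ Z
        b += Z.T @ Vi @ y
    cov = np.linalg.inv(A)
    return cov @ b, cov


def conditional_subject_means(dataset, beta, tau2, omega2, sigma2):
    """E[(intercept_i, effects_i) | y_i] by direct Gaussian conditioning
    on the joint covariance of (theta_i, y_i)."""
    blocks = _subject_blocks(dataset)
    p = blocks[0][0].shape[1]
    G = np.diag([tau2] + [omega2] * (p - 1))
    beta = np.asarray(beta, dtype=float)
    out = []
    for Z, y in blocks:
        V = sigma2 * np.eye(len(y)) + Z @ G @ Z.T
        cross = G @ Z.T  # cov(theta_i, y_i)
        out.append(beta + cross @ np.linalg.solve(V, y - Z @ beta))
    return np.array(out)
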