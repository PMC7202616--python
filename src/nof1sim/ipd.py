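"""Two-step individual-participant-data (IPD) meta-analysis.

Step one fits an ordinary least-squares regression of the outcome on the
condition indicators separately for every subject; with dummy coding this
is the subject's condition-mean differences.  Step two aggregates the
subject-level estimates with a (by default unit-)weighted mean, and takes
the weighted sample SD of the per-subject estimates as the
between-subject heterogeneity.  Because each per-subject estimate carries
its own sampling error, that sample SD systematically overstates the true
heterogeneity — the known positive bias of the two-step approach that the
one-step mixed models avoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .results import FitResult
from .trial_data import TrialDataset

__all__ = ["SubjectFit", "fit_subject_ols", "aggregate_ipd", "fit_ipd", "EstimationError"]


class EstimationError(RuntimeError):
    """Raised when a model cannot be estimated on the given data."""


@dataclass(frozen=True)
class SubjectFit:
    """Per-subject OLS results.

    ``effects`` holds the estimated treatment effect per non-reference
    condition; a condition the subject never provided a non-missing
    outcome for is absent (not estimable).  ``residual_variance`` uses
    denominator ``n_obs - n_parameters`` and is ``None`` when that is
    zero (saturated fit).
    """

    subject_id: str
    intercept: float
    effects: dict[str, float]
    residual_variance: float | None
    n_obs: int


def fit_subject_ols(
    frame: pd.DataFrame, conditions: tuple[str, ...], subject_id: str | None = None
) -> SubjectFit:
    """OLS of one subject's outcomes on their condition indicators.

    ``frame`` is the subject's slice of the long-format data; rows with
    missing outcomes are dropped.  Only conditions the subject actually
    has data for enter the regression.
    """
    obs = frame.dropna(subset=["outcome"])
    if len(obs) == 0:
        raise EstimationError(f"subject {subject_id}: no non-missing observations")
    if subject_id is None:
        subject_id = str(frame["subject"].iloc[0])
    present = [c for c in conditions if (obs["condition"] == c).any()]
    nonref = [c for c in present if c != conditions[0]]
    y = obs["outcome"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(obs))]
        + [(obs["condition"] == c).to_numpy(dtype=float) for c in nonref]
    )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df_resid = len(obs) - X.shape[1]
    resid_var = float(resid @ resid / df_resid) if df_resid > 0 else None
    # effects are meaningful only relative to an observed reference
    has_reference = conditions[0] in present
    effects = (
        {c: float(b) for c, b in zip(nonref, coef[1:])} if has_reference else {}
    )
    return SubjectFit(
        subject_id=subject_id,
        intercept=float(coef[0]),
        effects=effects,
        residual_variance=resid_var,
        n_obs=len(obs),
    )


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    return float(np.sum(weights * values) / np.sum(weights))


def _weighted_sd(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted sample SD; reduces to the ddof=1 sample SD for unit weights."""
    w = np.asarray(weights, dtype=float)
    W = w.sum()
    mean = np.sum(w * values) / W
    denom = W - np.sum(w**2) / W
    if denom <= 0:
        return 0.0
    return float(np.sqrt(np.sum(w * (values - mean) ** 2) / denom))


def aggregate_ipd(
    fits: list[SubjectFit],
    conditions: tuple[str, ...],
    weights: dict[str, float] | None = None,
) -> FitResult:
    """Weighted aggregation of per-subject fits into population estimates.

    Unit weights (the default) give the plain mean of the individual
    effects.  Subjects lacking a condition contribute to the intercept
    aggregation but not to that condition's effect aggregation; the
    ``diagnostics`` field records how many subjects each effect used.
    Per-subject predictions are the raw OLS estimates — the two-step
    method applies no shrinkage.
    """
    if weights is None:
        weights = {f.subject_id: 1.0 for f in fits}
    if any(weights.get(f.subject_id, 0.0) < 0 for f in fits):
        raise ValueError("weights must be nonnegative")
    if sum(weights.get(f.subject_id, 0.0) for f in fits) == 0:
        raise ValueError("all weights are zero")

    nonref = list(conditions[1:])
    n_estimable = sum(1 for f in fits if f.effects)
    if n_estimable < 2:
        raise EstimationError("need >= 2 subjects with estimable effects")

    w_all = np.array([weights.get(f.subject_id, 0.0) for f in fits])
    intercepts = np.array([f.intercept for f in fits])
    mu0 = _weighted_mean(intercepts, w_all)
    tau = _weighted_sd(intercepts, w_all)

    beta0: dict[str, float] = {}
    omega: dict[str, float] = {}
    used: dict[str, int] = {}
    subject_effects: dict[str, dict[str, float]] = {}
    for cond in nonref:
        have = [f for f in fits if cond in f.effects]
        if len(have) < 2:
            raise EstimationError(f"condition {cond}: < 2 subjects with estimable effects")
        vals = np.array([f.effects[cond] for f in have])
        w = np.array([weights.get(f.subject_id, 0.0) for f in have])
        beta0[cond] = _weighted_mean(vals, w)
        omega[cond] = _weighted_sd(vals, w)
        used[cond] = len(have)
        subject_effects[cond] = {f.subject_id: f.effects[cond] for f in have}

    resid = [
        (f.residual_variance, weights.get(f.subject_id, 0.0))
        for f in fits
        if f.residual_variance is not None
    ]
    if resid:
        rv, rw = map(np.array, zip(*resid))
        sigma2 = _weighted_mean(rv, rw)
    else:
        sigma2 = float("nan")

    return FitResult(
        method="ipd",
        mu0=mu0,
        beta0=beta0,
        tau=tau,
        omega=omega,
        sigma=float(np.sqrt(sigma2)),
        subject_intercepts={f.subject_id: f.intercept for f in fits},
        subject_effects=subject_effects,
        diagnostics={"subjects_per_effect": used, "n_subjects": len(fits)},
    )


def inverse_variance_weights(fits: list[SubjectFit]) -> dict[str, float]:
    """Optional 1/sigma2_i weights (NOT the default; unit weights are).

    Subjects with an undefined or zero residual variance get the largest
    finite weight observed, so saturated/noiseless fits are not dropped.
    """
    finite = [1.0 / f.residual_variance for f in fits if f.residual_variance]
    cap = max(finite) if finite else 1.0
    return {
        f.subject_id: (1.0 / f.residual_variance if f.residual_variance else cap)
        for f in fits
    }


def fit_ipd(dataset: TrialDataset, weights: dict[str, float] | None = None) -> FitResult:
    """Convenience wrapper: per-subject OLS then weighted aggregation."""
    fits = [
        fit_subject_ols(dataset.subject_frame(s), dataset.conditions, subject_id=s)
        for s in dataset.subjects
    ]
    return aggregate_ipd(fits, dataset.conditions, weights=weights)
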