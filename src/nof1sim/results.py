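"""Common output contract for all three estimation methods."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["FitResult"]


@dataclass
class FitResult:
    """Population and per-subject estimates from any fitting method.

    Population-level fields mirror the hierarchical model: intercept
    ``mu0``, per-condition average treatment effect ``beta0``,
    between-subject intercept SD ``tau``, between-subject effect SD
    ``omega`` per condition, residual SD ``sigma``.  Per-subject effects
    are on the absolute scale (population effect plus the subject's
    deviation).  For the two-step IPD method the per-subject values are
    the raw per-subject regression estimates (no shrinkage); for the
    mixed models they are empirical-Bayes / posterior-mean predictions.
    """

    method: str
    mu0: float
    beta0: dict[str, float]
    tau: float
    omega: dict[str, float]
    sigma: float
    subject_intercepts: dict[str, float] = field(default_factory=dict)
    subject_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0
    diagnostics: dict = field(default_factory=dict)

    def effect(self, condition: str | None = None) -> float:
        """Population effect for one condition (the only one if omitted)."""
        if condition is None:
            (condition,) = self.beta0
        return self.beta0[condition]

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per population parameter and per subject effect."""
        rows = [
            {"level": "population", "parameter": "mu0", "condition": "", "value": self.mu0},
            {"level": "population", "parameter": "tau", "condition": "", "value": self.tau},
            {"level": "population", "parameter": "sigma", "condition": "", "value": self.sigma},
        ]
        for cond, val in self.beta0.items():
            rows.append(
                {"level": "population", "parameter": "beta0", "condition": cond, "value": val}
            )
        for cond, val in self.omega.items():
            rows.append(
                {"level": "population", "parameter": "omega", "condition": cond, "value": val}
            )
        for sid, val in self.subject_intercepts.items():
            rows.append(
                {"level": f"subject:{sid}", "parameter": "intercept", "condition": "", "value": val}
            )
        for cond, per_subject in self.subject_effects.items():
            for sid, val in per_subject.items():
                rows.append(
                    {"level": f"subject:{sid}", "parameter": "effect", "condition": cond, "value": val}
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
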