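"""Hierarchical-model simulator for N-of-1 crossover trials.

Data are generated from a two-level linear mixed model.  For subject
``i`` at occasion ``j``::

    Y_ij = mu0 + mu_i + X_ij * beta_i + eps_ij
    eps_ij ~ N(0, sigma2)          residual noise
    mu_i   ~ N(0, tau2)            subject's intercept deviation
    beta_i ~ N(beta0, omega2)      subject's treatment effect

``X_ij`` is the 0/1 treatment indicator.  Each subject contributes an
equal number of control and treatment measurements; the within-subject
order of conditions is a uniformly random interleaving, different for
every subject.  The default population parameters place the control mean
at 0 with between-subject intercept SD 1, the average treatment effect at
-2 with between-subject effect SD 0.5, and residual SD 1 — i.e. SD ratios
of 1:1 (intercept : residual) and 0.5:1 (effect : residual).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trial_data import TrialDataset, make_dataset

__all__ = [
    "PopulationParameters",
    "ScenarioSpec",
    "SubjectTruth",
    "simulate_dataset",
    "scenario_grid",
    "CONTROL",
    "TREATMENT",
]

CONTROL = "control"
TREATMENT = "treatment"


@dataclass(frozen=True)
class PopulationParameters:
    """Generating parameters of the hierarchical model.

    Defaults are the simulation-study conditions: ``mu0=0``, ``tau2=1``,
    ``beta0=-2``, ``omega2=0.25`` (between-subject effect SD 0.5) and
    ``sigma2=1``.
    """

    mu0: float = 0.0
    tau2: float = 1.0
    beta0: float = -2.0
    omega2: float = 0.25
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if self.tau2 < 0 or self.omega2 < 0:
            raise ValueError("variance components must be >= 0")
        if self.sigma2 < 0:
            raise ValueError("residual variance must be >= 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of a simulation experiment.

    ``t_per_condition`` is the number of measurements in EACH condition,
    so a subject contributes ``2 * t_per_condition`` observations.  Set
    ``t_is_total=True`` for the alternative reading in which ``t`` is the
    total per-subject count split evenly over the two conditions
    (requires an even ``t``).
    """

    n_subjects: int
    t_per_condition: int
    replicates: int = 1000
    seed: int = 0
    params: PopulationParameters = field(default_factory=PopulationParameters)
    name: str = ""
    t_is_total: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.t_per_condition < 1:
            raise ValueError("need at least 1 measurement per condition")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.t_is_total and self.t_per_condition % 2:
            raise ValueError("t_is_total requires an even t")

    @property
    def t_each(self) -> int:
        """Measurements per condition after resolving the t interpretation."""
        return self.t_per_condition // 2 if self.t_is_total else self.t_per_condition

    @property
    def label(self) -> str:
        return self.name or f"n{self.n_subjects}_t{self.t_per_condition}"


@dataclass(frozen=True)
class SubjectTruth:
    """Ground-truth random effects drawn for one simulated subject."""

    subject_id: str
    mu_i: float  # intercept deviation from mu0
    beta_i: float  # treatment effect (absolute scale)


def _replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    # substream keyed by (seed, replicate) so any replicate is reproducible
    # in isolation and scaled-down runs are prefixes of full runs
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate_index)]))


def simulate_dataset(
    scenario: ScenarioSpec, replicate_index: int = 0
) -> tuple[TrialDataset, list[SubjectTruth]]:
    """Draw one replicate dataset plus its ground-truth effects.

    The RNG stream is fully determined by ``(scenario.seed,
    replicate_index)``: the same pair always yields a bit-identical
    dataset.
    """
    p = scenario.params
    rng = _replicate_rng(scenario.seed, replicate_index)
    t = scenario.t_each
    n = scenario.n_subjects
    width = len(str(n))

    frames = []
    truths = []
    for i in range(n):
        sid = f"s{i + 1:0{width}d}"
        mu_i = rng.normal(0.0, np.sqrt(p.tau2))
        beta_i = rng.normal(p.beta0, np.sqrt(p.omega2))
        x = rng.permutation(np.repeat([0.0, 1.0], t))
        y = p.mu0 + mu_i + x * beta_i + rng.normal(0.0, np.sqrt(p.sigma2), size=2 * t)
        frames.append(
            pd.DataFrame(
                {
                    "subject": sid,
                    "time": np.arange(1, 2 * t + 1),
                    "condition": np.where(x > 0, TREATMENT, CONTROL),
                    "outcome": y,
                }
            )
        )
        truths.append(SubjectTruth(subject_id=sid, mu_i=mu_i, beta_i=beta_i))
    dataset = make_dataset(
        pd.concat(frames, ignore_index=True), conditions=(CONTROL, TREATMENT)
    )
    return dataset, truths


def scenario_grid(
    replicates: int = 1000,
    seed: int = 0,
    params: PopulationParameters | None = None,
) -> list[ScenarioSpec]:
    """The 3x3 grid of study sizes: n in {20,30,40} x t in {10,20,30}.

    All nine cells share the fixed population parameters; only the number
    of subjects and the measurements per condition vary.
    """
    params = params or PopulationParameters()
    grid = []
    for n in (20, 30, 40):
        for t in (10, 20, 30):
            grid.append(
                ScenarioSpec(
                    n_subjects=n,
                    t_per_condition=t,
                    replicates=replicates,
                    seed=seed,
                    params=params,
                )
            )
    return grid
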