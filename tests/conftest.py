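import numpy as np
import pandas as pd
import pytest

import nof1sim as n
from nof1sim.trial_data import make_dataset

# scale of the shared simulation experiments (scaled down from the full
# 1000-replicate design; replicate substreams make short runs prefixes
# of long ones)
N_REPLICATES = 200
EXPERIMENT_SEED = 1


def dataset_from_rows(rows, conditions=None):
    return make_dataset(pd.DataFrame(rows), conditions=conditions)


def two_condition_dataset(per_subject: dict, conditions=("control", "treatment")):
    """Build a dataset from {subject: {condition: [outcomes]}} mappings."""
    rows = []
    for sid, conds in per_subject.items():
        t = 1
        for cond, values in conds.items():
            for v in values:
                rows.append(
                    {"subject": sid, "time": t, "condition": cond, "outcome": v}
                )
                t += 1
    return dataset_from_rows(rows, conditions=conditions)


@pytest.fixture(scope="session")
def toy_2subject():
    """Balanced 2-subject, 8-observations-each toy with known noise."""
    rng = np.random.default_rng(42)
    rows = []
    for sid in ("a", "b"):
        for j, cond in enumerate(["control"] * 4 + ["treatment"] * 4, start=1):
            mean = -2.0 if cond == "treatment" else 0.0
            rows.append(
                {"subject": sid, "time": j, "condition": cond,
                 "outcome": rng.normal(mean, 1.0)}
            )
    return dataset_from_rows(rows, conditions=("control", "treatment"))


@pytest.fixture(scope="session")
def toy_3subject():
    """3 subjects x 4 observations, identifiable but tiny."""
    rng = np.random.default_rng(7)
    rows = []
    for sid in ("a", "b", "c"):
        for j, cond in enumerate(["control", "treatment", "control", "treatment"], start=1):
            mean = -2.0 if cond == "treatment" else 0.0
            rows.append(
                {"subject": sid, "time": j, "condition": cond,
                 "outcome": rng.normal(mean, 1.0)}
            )
    return dataset_from_rows(rows, conditions=("control", "treatment"))


@pytest.fixture(scope="session")
def recovery_estimates():
    """Frequentist ML estimates over replicates of the largest scenario.

    The scaled-down parameter-recovery experiment: 40 subjects, 30
    measurements per condition, N_REPLICATES replicate datasets, one
    ML mixed-model fit each.
    """
    scenario = n.ScenarioSpec(
        n_subjects=40, t_per_condition=30, replicates=N_REPLICATES,
        seed=EXPERIMENT_SEED,
    )
    rows = []
    for rep in range(N_REPLICATES):
        dataset, _ = n.simulate_dataset(scenario, rep)
        fit = n.fit_lme_ml(dataset)
        rows.append(
            {
                "beta0": fit.beta0["treatment"],
                "omega": fit.omega["treatment"],
                "tau2": fit.tau**2,
                "sigma2": fit.sigma**2,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def corner_comparisons():
    """Paired IPD vs F-LME runs on the four corner scenarios of the grid."""
    out = {}
    for n_subj in (20, 40):
        for t in (10, 30):
            scenario = n.ScenarioSpec(
                n_subjects=n_subj, t_per_condition=t,
                replicates=N_REPLICATES, seed=EXPERIMENT_SEED,
            )
            out[(n_subj, t)] = n.run_scenario(
                scenario, methods=("ipd", "flme"), replicates=N_REPLICATES
            )
    return out
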