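import numpy as np
import pandas as pd
import pytest

import nof1sim as n
from conftest import two_condition_dataset
from nof1sim.ipd import EstimationError, SubjectFit, fit_subject_ols, inverse_variance_weights


def _subject_frame(control, treatment):
    rows = []
    for i, v in enumerate(control, start=1):
        rows.append({"subject": "s", "time": i, "condition": "control", "outcome": v})
    for i, v in enumerate(treatment, start=len(control) + 1):
        rows.append({"subject": "s", "time": i, "condition": "treatment", "outcome": v})
    return pd.DataFrame(rows)


@pytest.mark.parametrize(
    "control, treatment, intercept, effect, resid_var",
    [
        ([5.0, 5.0], [3.0, 3.0], 5.0, -2.0, 0.0),   # noiseless two-mean case
        ([1.0, 3.0], [2.0, 6.0], 2.0, 2.0, 5.0),    # residual SS (1+1+4+4)/2
        ([4.0], [7.0], 4.0, 3.0, None),              # saturated fit, df = 0
    ],
)
def test_subject_ols_closed_form(control, treatment, intercept, effect, resid_var):
    fit = fit_subject_ols(_subject_frame(control, treatment), ("control", "treatment"))
    assert fit.intercept == pytest.approx(intercept)
    assert fit.effects["treatment"] == pytest.approx(effect)
    if resid_var is None:
        assert fit.residual_variance is None
    else:
        assert fit.residual_variance == pytest.approx(resid_var)


def test_subject_ols_no_observations_errors():
    frame = _subject_frame([np.nan], [np.nan])
    with pytest.raises(EstimationError):
        fit_subject_ols(frame, ("control", "treatment"), subject_id="s")


def test_subject_without_reference_has_no_effect():
    frame = pd.DataFrame(
        [{"subject": "s", "time": 1, "condition": "treatment", "outcome": 4.0},
         {"subject": "s", "time": 2, "condition": "treatment", "outcome": 6.0}]
    )
    fit = fit_subject_ols(frame, ("control", "treatment"))
    assert fit.effects == {}


def _fit(sid, intercept, effect, rv=1.0):
    return SubjectFit(subject_id=sid, intercept=intercept,
                      effects={"treatment": effect}, residual_variance=rv, n_obs=4)


def test_aggregate_two_subjects_mean_and_sd():
    fits = [_fit("a", 1.0, -1.0), _fit("b", 3.0, -3.0)]
    res = n.aggregate_ipd(fits, ("control", "treatment"))
    assert res.beta0["treatment"] == pytest.approx(-2.0)
    assert res.omega["treatment"] == pytest.approx(np.sqrt(2.0))
    assert res.mu0 == pytest.approx(2.0)
    assert res.tau == pytest.approx(np.sqrt(2.0))


def test_identical_subjects_give_zero_heterogeneity():
    fits = [_fit(s, 2.0, -1.5) for s in "abcd"]
    res = n.aggregate_ipd(fits, ("control", "treatment"))
    assert res.omega["treatment"] == 0.0
    assert res.tau == 0.0


def test_unit_weights_equal_omitted_weights():
    fits = [_fit("a", 1.0, -1.0), _fit("b", 3.0, -3.0), _fit("c", 0.0, -2.0)]
    res_default = n.aggregate_ipd(fits, ("control", "treatment"))
    res_unit = n.aggregate_ipd(
        fits, ("control", "treatment"), weights={"a": 1.0, "b": 1.0, "c": 1.0}
    )
    assert res_default.beta0 == res_unit.beta0
    assert res_default.omega == res_unit.omega
    assert res_default.tau == res_unit.tau
    assert res_default.sigma == res_unit.sigma


def test_aggregation_permutation_invariant():
    fits = [_fit("a", 1.0, -1.0), _fit("b", 3.0, -3.0), _fit("c", 0.0, -2.0)]
    res1 = n.aggregate_ipd(fits, ("control", "treatment"))
    res2 = n.aggregate_ipd(fits[::-1], ("control", "treatment"))
    assert res1.beta0["treatment"] == pytest.approx(res2.beta0["treatment"])
    assert res1.omega["treatment"] == pytest.approx(res2.omega["treatment"])
    assert res1.mu0 == pytest.approx(res2.mu0)


def test_subject_missing_condition_counts_for_intercept_only():
    fits = [
        _fit("a", 1.0, -1.0),
        _fit("b", 3.0, -3.0),
        SubjectFit(subject_id="c", intercept=10.0, effects={},
                   residual_variance=1.0, n_obs=2),
    ]
    res = n.aggregate_ipd(fits, ("control", "treatment"))
    assert res.mu0 == pytest.approx((1.0 + 3.0 + 10.0) / 3)
    assert res.beta0["treatment"] == pytest.approx(-2.0)
    assert res.diagnostics["subjects_per_effect"]["treatment"] == 2
    assert "c" not in res.subject_effects["treatment"]


def test_aggregation_error_paths():
    with pytest.raises(EstimationError):
        n.aggregate_ipd([_fit("a", 1.0, -1.0)], ("control", "treatment"))
    fits = [_fit("a", 1.0, -1.0), _fit("b", 3.0, -3.0)]
    with pytest.raises(ValueError):
        n.aggregate_ipd(fits, ("control", "treatment"), weights={"a": 0.0, "b": 0.0})
    with pytest.raises(ValueError):
        n.aggregate_ipd(fits, ("control", "treatment"), weights={"a": -1.0, "b": 1.0})


def test_inverse_variance_weighting_is_an_option_not_default():
    ds = two_condition_dataset(
        {"a": {"control": [1.0, 3.0], "treatment": [2.0, 6.0]},
         "b": {"control": [5.0, 5.2], "treatment": [3.0, 3.1]}}
    )
    default = n.fit_ipd(ds)
    fits = [
        fit_subject_ols(ds.subject_frame(s), ds.conditions, subject_id=s)
        for s in ds.subjects
    ]
    weighted = n.aggregate_ipd(fits, ds.conditions, weights=inverse_variance_weights(fits))
    # subject b is far less noisy, so weighting pulls beta0 toward its effect
    assert weighted.beta0["treatment"] != pytest.approx(default.beta0["treatment"])
    assert abs(weighted.beta0["treatment"] - (-2.05)) < abs(
        default.beta0["treatment"] - (-2.05)
    )


def test_identical_noiseless_subjects_all_methods_agree():
    """With zero heterogeneity and zero noise, the two-step and one-step
    estimators coincide at the exact population values."""
    ds = two_condition_dataset(
        {s: {"control": [5.0, 5.0], "treatment": [3.0, 3.0]} for s in "abc"}
    )
    ipd = n.fit_ipd(ds)
    flme = n.fit_lme_ml(ds)
    assert ipd.mu0 == pytest.approx(5.0)
    assert ipd.beta0["treatment"] == pytest.approx(-2.0)
    assert flme.mu0 == pytest.approx(5.0, abs=1e-6)
    assert flme.beta0["treatment"] == pytest.approx(-2.0, abs=1e-6)
    _, blme = n.fit_lme_bayes(ds, seed=5, chains=2, warmup=300, draws=300)
    assert blme.mu0 == pytest.approx(5.0, abs=0.05)
    assert blme.beta0["treatment"] == pytest.approx(-2.0, abs=0.05)
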