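import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nof1sim as n
from conftest import dataset_from_rows, two_condition_dataset
from nof1sim.trial_data import TrialFormatError, make_dataset

MINIMAL_CSV = """subject,time,condition,outcome
s1,1,control,5.0
s1,2,treatment,3.0
s2,1,control,6.0
s2,2,treatment,4.0
"""


def test_read_minimal_csv(tmp_path):
    path = tmp_path / "d.csv"
    path.write_text(MINIMAL_CSV)
    ds = n.read_trial_csv(path)
    assert ds.n_subjects == 2
    assert ds.conditions == ("control", "treatment")
    assert not ds.data["outcome"].isna().any()


def test_missing_outcome_cell_retained(tmp_path):
    path = tmp_path / "d.csv"
    path.write_text(MINIMAL_CSV.replace("s1,2,treatment,3.0", "s1,2,treatment,"))
    ds = n.read_trial_csv(path)
    assert int(ds.data["outcome"].isna().sum()) == 1
    assert "s1" in ds.subjects


def test_non_numeric_outcome_reports_line(tmp_path):
    path = tmp_path / "d.csv"
    path.write_text(MINIMAL_CSV.replace("6.0", "oops"))
    with pytest.raises(TrialFormatError, match="line 4"):
        n.read_trial_csv(path)


def test_missing_column_is_format_error(tmp_path):
    path = tmp_path / "d.csv"
    path.write_text("subject,time,outcome\ns1,1,5.0\n")
    with pytest.raises(TrialFormatError, match="condition"):
        n.read_trial_csv(path)


def test_column_mapping(tmp_path):
    path = tmp_path / "d.csv"
    path.write_text(
        "id,day,arm,weight\ns1,1,ctl,5.0\ns1,2,trt,3.0\ns2,1,ctl,6.0\ns2,2,trt,4.0\n"
    )
    ds = n.read_trial_csv(
        path, columns={"subject": "id", "time": "day", "condition": "arm",
                       "outcome": "weight"}
    )
    assert ds.conditions == ("ctl", "trt")


@pytest.mark.parametrize("source", ["simulated", "empirical_fixture"])
def test_csv_round_trip_identity(tmp_path, source):
    if source == "simulated":
        ds, _ = n.simulate_dataset(
            n.ScenarioSpec(n_subjects=5, t_per_condition=4, seed=3), 0
        )
    else:
        ds = n.generate_empirical_fixture(seed=3)
        assert ds.n_subjects == 12
        assert len(ds.conditions) == 3
        assert ds.data.groupby("subject")["time"].nunique().eq(63).all()
    path = tmp_path / "rt.csv"
    n.write_trial_csv(ds, path)
    assert n.read_trial_csv(path, conditions=ds.conditions) == ds


def test_missing_written_as_empty_cell(tmp_path):
    ds = dataset_from_rows(
        [
            {"subject": "a", "time": 1, "condition": "c", "outcome": 1.0},
            {"subject": "a", "time": 2, "condition": "t", "outcome": None},
            {"subject": "b", "time": 1, "condition": "c", "outcome": 2.0},
            {"subject": "b", "time": 2, "condition": "t", "outcome": 3.0},
        ]
    )
    path = tmp_path / "m.csv"
    n.write_trial_csv(ds, path)
    lines = path.read_text().splitlines()
    assert lines[2] == "a,2,t,"


def test_degenerate_datasets_rejected():
    with pytest.raises(TrialFormatError):
        make_dataset(pd.DataFrame(columns=["subject", "time", "condition", "outcome"]))
    with pytest.raises(TrialFormatError):
        dataset_from_rows(
            [
                {"subject": "a", "time": 1, "condition": "c", "outcome": None},
                {"subject": "a", "time": 2, "condition": "t", "outcome": None},
            ]
        )
    with pytest.raises(TrialFormatError):
        dataset_from_rows(  # duplicated time within subject
            [
                {"subject": "a", "time": 1, "condition": "c", "outcome": 1.0},
                {"subject": "a", "time": 1, "condition": "t", "outcome": 2.0},
            ]
        )


def test_design_matrix_binary_and_row_count():
    ds = two_condition_dataset(
        {"a": {"control": [1.0, None], "treatment": [2.0]},
         "b": {"control": [3.0], "treatment": [4.0]}}
    )
    dm = n.design_matrix(ds)
    assert dm.X.shape == (4, 1)
    assert dm.n_obs == int(ds.data["outcome"].notna().sum())
    assert set(np.unique(dm.X)) <= {0.0, 1.0}


def test_design_matrix_three_conditions_reference_rows_zero():
    rows = []
    for sid in ("a", "b"):
        for t, cond in enumerate(["ref", "c2", "c3"], start=1):
            rows.append({"subject": sid, "time": t, "condition": cond,
                         "outcome": float(t)})
    dm = n.design_matrix(dataset_from_rows(rows, conditions=("ref", "c2", "c3")))
    assert dm.condition_labels == ["c2", "c3"]
    ref_rows = dm.X[::3]  # every subject's first row is the reference
    assert (ref_rows == 0).all()


def test_design_matrix_excludes_all_missing_subject():
    ds = dataset_from_rows(
        [
            {"subject": "a", "time": 1, "condition": "c", "outcome": 1.0},
            {"subject": "a", "time": 2, "condition": "t", "outcome": 2.0},
            {"subject": "b", "time": 1, "condition": "c", "outcome": None},
            {"subject": "b", "time": 2, "condition": "t", "outcome": None},
        ],
        conditions=("c", "t"),
    )
    dm = n.design_matrix(ds)
    assert dm.subjects == ["a"]
    assert dm.n_obs == 2


def test_condition_order_swap_changes_nothing_in_mapping():
    # same labels, opposite calendar order: indicator depends on the label only
    ds = dataset_from_rows(
        [
            {"subject": "a", "time": 1, "condition": "c", "outcome": 1.0},
            {"subject": "a", "time": 2, "condition": "t", "outcome": 2.0},
            {"subject": "b", "time": 1, "condition": "t", "outcome": 3.0},
            {"subject": "b", "time": 2, "condition": "c", "outcome": 4.0},
        ],
        conditions=("c", "t"),
    )
    dm = n.design_matrix(ds)
    by_label = {
        (sid, t): x
        for sid, t, x in zip(
            ds.data["subject"], ds.data["time"], dm.X[:, 0]
        )
    }
    assert by_label[("a", 2)] == by_label[("b", 1)] == 1.0
    assert by_label[("a", 1)] == by_label[("b", 2)] == 0.0


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    outcomes=st.lists(
        st.one_of(
            st.none(),
            st.floats(min_value=-1e6, max_value=1e6,
                      allow_nan=False, allow_infinity=False),
        ),
        min_size=2, max_size=12,
    )
)
def test_round_trip_is_identity_property(tmp_path_factory, outcomes):
    if all(v is None for v in outcomes):
        outcomes = outcomes + [1.0]
    rows = [
        {"subject": f"s{i % 3}", "time": i // 3 + 1,
         "condition": "c" if i % 2 else "t", "outcome": v}
        for i, v in enumerate(outcomes)
    ]
    ds = dataset_from_rows(rows, conditions=("c", "t"))
    path = tmp_path_factory.mktemp("rt") / "d.csv"
    n.write_trial_csv(ds, path)
    assert n.read_trial_csv(path, conditions=("c", "t")) == ds
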