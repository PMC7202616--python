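"""Long-format N-of-1 trial data container and CSV I/O.

An N-of-1 trial records repeated measurements of a continuous outcome on a
single subject while the subject crosses over between a reference (control)
condition and one or more treatment conditions.  A multi-subject study is a
collection of such trials.  The canonical on-disk representation is a tidy
CSV with one row per (subject, time) measurement occasion::

    subject,time,condition,outcome
    s01,1,control,71.2
    s01,2,treatment,

An empty ``outcome`` field denotes a missing measurement; missing rows are
kept in the dataset (the occasion happened, the value was not recorded) but
are excluded from every likelihood and regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialDataset",
    "DesignMatrix",
    "TrialFormatError",
    "read_trial_csv",
    "write_trial_csv",
    "design_matrix",
]

#: logical -> physical column names used when no mapping is given
DEFAULT_COLUMNS = {
    "subject": "subject",
    "time": "time",
    "condition": "condition",
    "outcome": "outcome",
}


class TrialFormatError(ValueError):
    """Raised when trial data violate the format contract."""


@dataclass(frozen=True)
class TrialDataset:
    """Immutable long-format trial dataset.

    Parameters
    ----------
    data
        DataFrame with columns ``subject`` (str), ``time`` (int, 1-based
        within-subject measurement index), ``condition`` (str) and
        ``outcome`` (float, NaN = missing).
    conditions
        Ordered condition labels; the first entry is the reference
        (control) condition, all others are dummy-coded against it.
    """

    data: pd.DataFrame
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in DEFAULT_COLUMNS if c not in df.columns]
        if missing_cols:
            raise TrialFormatError(f"missing columns: {missing_cols}")
        if len(df) == 0:
            raise TrialFormatError("dataset has no observations")
        if len(self.conditions) < 2:
            raise TrialFormatError("need a reference condition and at least one other")
        extra = set(df["condition"]) - set(self.conditions)
        if extra:
            raise TrialFormatError(f"conditions not in declared set: {sorted(extra)}")
        dup = df.duplicated(subset=["subject", "time"])
        if dup.any():
            raise TrialFormatError("time index not unique within subject")
        if df["outcome"].isna().all():
            raise TrialFormatError("dataset has no non-missing outcomes")

    # -- conveniences -------------------------------------------------

    @property
    def reference(self) -> str:
        return self.conditions[0]

    @property
    def subjects(self) -> list[str]:
        """Subject labels in order of first appearance."""
        return list(dict.fromkeys(self.data["subject"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def observation_counts(self) -> pd.Series:
        """Non-missing observation count per subject."""
        return self.data.dropna(subset=["outcome"]).groupby("subject").size()

    def subject_frame(self, subject: str) -> pd.DataFrame:
        return self.data[self.data["subject"] == subject]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialDataset):
            return NotImplemented
        return self.conditions == other.conditions and self.data.reset_index(
            drop=True
        ).equals(other.data.reset_index(drop=True))


@dataclass(frozen=True)
class DesignMatrix:
    """Dummy-coded regression arrays for the non-missing observations.

    ``X`` has one 0/1 column per non-reference condition (columns in
    ``condition_labels`` order); reference-condition rows are all zero.
    Rows are ordered by subject (first appearance) then time index.
    """

    X: np.ndarray
    y: np.ndarray
    subject_index: np.ndarray  # integer code into `subjects` per row
    subjects: list[str]
    condition_labels: list[str]  # non-reference conditions

    @property
    def n_obs(self) -> int:
        return len(self.y)


def make_dataset(
    df: pd.DataFrame, conditions: Sequence[str] | None = None
) -> TrialDataset:
    """Normalise a raw frame (dtypes, declared condition set) into a dataset."""
    df = df.copy()
    df["subject"] = df["subject"].astype(str)
    df["time"] = df["time"].astype(int)
    df["condition"] = df["condition"].astype(str)
    df["outcome"] = pd.to_numeric(df["outcome"], errors="raise").astype(float)
    if conditions is None:
        conditions = tuple(dict.fromkeys(df["condition"]))
    return TrialDataset(data=df.reset_index(drop=True), conditions=tuple(conditions))


def read_trial_csv(
    path,
    columns: Mapping[str, str] | None = None,
    conditions: Sequence[str] | None = None,
) -> TrialDataset:
    """Read a long-format trial CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    columns
        Optional mapping from the logical names ``subject``, ``time``,
        ``condition``, ``outcome`` to the file's actual column names, for
        files whose layout differs from the default.
    conditions
        Optional declared condition set (reference first); inferred in
        first-appearance order when omitted.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing required column(s) {missing}")
    df = pd.DataFrame(
        {logical: raw[actual] for logical, actual in colmap.items()}
    )
    outcome_str = df["outcome"].str.strip()

    def _parse(s: str) -> float:
        # Python's float() is correctly rounded, so write/read is lossless
        if s == "":
            return np.nan
        try:
            return float(s)
        except ValueError:
            return np.nan

    numeric = outcome_str.map(_parse)
    bad = outcome_str.ne("") & numeric.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise TrialFormatError(
            f"{path}: non-numeric outcome {outcome_str[bad].iloc[0]!r} on line {row}"
        )
    df["outcome"] = numeric
    try:
        df["time"] = df["time"].astype(int)
    except ValueError as exc:
        raise TrialFormatError(f"{path}: non-integer time index ({exc})") from exc
    return make_dataset(df, conditions=conditions)


def write_trial_csv(dataset: TrialDataset, path) -> None:
    """Write a dataset so that :func:`read_trial_csv` reproduces it exactly.

    Missing outcomes become empty cells; floats use full repr precision so
    the round trip is lossless.
    """
    out = dataset.data[["subject", "time", "condition", "outcome"]].copy()
    # 17 significant digits guarantee float64 round-trips losslessly
    out["outcome"] = out["outcome"].map(
        lambda v: "" if pd.isna(v) else np.format_float_positional(
            v, precision=None, unique=True, trim="0"
        )
    )
    out.to_csv(path, index=False)


def design_matrix(dataset: TrialDataset) -> DesignMatrix:
    """Dummy-code the dataset for regression, dropping missing outcomes.

    Indicators depend only on the condition label, never on when the
    condition occurred, so subjects who received the conditions in a
    different order map onto the same columns.
    """
    subjects = dataset.subjects
    order = {s: i for i, s in enumerate(subjects)}
    df = dataset.data.dropna(subset=["outcome"]).copy()
    df["_s"] = df["subject"].map(order)
    df = df.sort_values(["_s", "time"], kind="stable")
    nonref = list(dataset.conditions[1:])
    X = np.column_stack(
        [(df["condition"] == c).to_numpy(dtype=float) for c in nonref]
    )
    used = sorted(set(df["_s"]))
    # subjects whose outcomes are all missing contribute zero rows
    kept_subjects = [subjects[i] for i in used]
    recode = {old: new for new, old in enumerate(used)}
    return DesignMatrix(
        X=X,
        y=df["outcome"].to_numpy(dtype=float),
        subject_index=df["_s"].map(recode).to_numpy(dtype=int),
        subjects=kept_subjects,
        condition_labels=nonref,
    )
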