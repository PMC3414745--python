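"""Long-format repeated-measures dataset, wide pivoting and balance checks.

The canonical container is long format -- one row per measurement
``(subject, group, time, response)`` -- because the mixed-model and
summary-measure analyses accept unbalanced data with subject-specific time
grids.  The wide ``N x m`` matrix required by the multivariate (profile
analysis) route is derived, and only constructible from balanced, complete
data on a shared time grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError, FeasibilityError

logger = logging.getLogger(__name__)

#: canonical column names of the long format
LONG_COLUMNS = ("subject", "group", "time", "response")


@dataclass(frozen=True)
class RepeatedMeasuresDataset:
    """A collection of repeated measurements in long format.

    Parameters
    ----------
    data
        DataFrame with columns ``subject, group, time, response``; one row
        per measurement.  ``time`` and ``response`` are numeric; subject and
        group labels are opaque.

    Invariants (checked on construction):

    * each ``(subject, time)`` pair appears at most once;
    * every subject belongs to exactly one group.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing required columns: {missing}")
        df = df.loc[:, list(LONG_COLUMNS)].reset_index(drop=True)
        df["time"] = pd.to_numeric(df["time"]).astype(float)
        df["response"] = pd.to_numeric(df["response"]).astype(float)
        dup = df.duplicated(subset=["subject", "time"], keep=False)
        if dup.any():
            bad = sorted(df.loc[dup, "subject"].unique().tolist())
            raise DataError(
                f"duplicate (subject, time) measurements for subject(s): {bad}"
            )
        multi = df.groupby("subject", sort=False)["group"].nunique()
        if (multi > 1).any():
            bad = sorted(multi.index[multi > 1].tolist())
            raise DataError(f"subject(s) assigned to more than one group: {bad}")
        object.__setattr__(self, "data", df)

    # -- derived metadata ---------------------------------------------------

    @property
    def subjects(self) -> list:
        """Subject labels in order of first appearance."""
        return self.data["subject"].unique().tolist()

    @property
    def n_subjects(self) -> int:
        return self.data["subject"].nunique()

    @property
    def groups(self) -> list:
        """Distinct group labels, sorted lexicographically."""
        return sorted(self.data["group"].unique().tolist())

    @property
    def n_groups(self) -> int:
        return self.data["group"].nunique()

    @property
    def group_sizes(self) -> dict:
        """Number of subjects per group."""
        per = self.data.drop_duplicates("subject").groupby("group").size()
        return per.to_dict()

    @property
    def measurements_per_subject(self) -> dict:
        return self.data.groupby("subject", sort=False).size().to_dict()

    @property
    def time_grid(self) -> np.ndarray:
        """Sorted union of all observed time values."""
        return np.sort(self.data["time"].unique())

    def subject_records(self):
        """Yield ``(subject, group, times, responses)`` per subject, times sorted."""
        for subj, sub in self.data.groupby("subject", sort=False):
            sub = sub.sort_values("time")
            yield (
                subj,
                sub["group"].iloc[0],
                sub["time"].to_numpy(float),
                sub["response"].to_numpy(float),
            )

    def is_complete(self) -> bool:
        """True when every subject is measured at every time of the union grid."""
        m = len(self.time_grid)
        counts = self.data.groupby("subject", sort=False)["time"].nunique()
        return bool((counts == m).all())


@dataclass(frozen=True)
class WideMatrix:
    """Balanced-and-complete ``N x m`` response matrix on a shared time grid."""

    subjects: list
    groups: np.ndarray  # group label per subject, aligned with rows
    times: np.ndarray  # strictly increasing, length m
    values: np.ndarray  # shape (N, m)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, float)
        times = np.asarray(self.times, float)
        if values.shape != (len(self.subjects), times.size):
            raise DataError("wide matrix shape does not match subjects/times")
        if np.any(np.diff(times) <= 0):
            raise DataError("wide time grid must be strictly increasing")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "groups", np.asarray(self.groups))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


def read_long(
    path,
    column_map: dict | None = None,
    sep: str | None = None,
) -> RepeatedMeasuresDataset:
    """Read a delimited long-format file into a dataset.

    Parameters
    ----------
    path
        CSV (default) or TSV file with a header row.
    column_map
        Optional mapping from canonical names (``subject``, ``group``,
        ``time``, ``response``) to the column names used in the file.
    sep
        Field separator; ``None`` autodetects comma vs tab from the header.

    Rows with a missing response are dropped (and counted in the log).
    """
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    column_map = column_map or {}
    rename = {}
    for canon in LONG_COLUMNS:
        src = column_map.get(canon, canon)
        if src not in df.columns:
            raise ConfigurationError(
                f"column {src!r} (for {canon!r}) not found in {path}; "
                f"available: {list(df.columns)}"
            )
        rename[src] = canon
    df = df.rename(columns=rename)
    n_missing = int(df["response"].isna().sum())
    if n_missing:
        logger.warning("dropped %d rows with missing response", n_missing)
        df = df.dropna(subset=["response"])
    return RepeatedMeasuresDataset(df)


def write_long(ds: RepeatedMeasuresDataset, path, sep: str = ",") -> None:
    """Write the dataset back to delimited text (full float precision)."""
    ds.data.to_csv(path, sep=sep, index=False, float_format="%.17g")


def to_wide(ds: RepeatedMeasuresDataset) -> WideMatrix:
    """Pivot to the ``N x m`` wide matrix required by the multivariate route.

    Raises
    ------
    FeasibilityError
        If any subject misses a cell of the shared time grid (no imputation
        is ever attempted; use :func:`complete_case_subset` first to restrict
        to complete cases).
    """
    grid = ds.time_grid
    m = grid.size
    counts = ds.data.groupby("subject", sort=False)["time"].nunique()
    incomplete = counts.index[counts < m].tolist()
    if incomplete:
        raise FeasibilityError(
            f"{len(incomplete)} subject(s) lack measurements on the shared "
            f"{m}-point time grid: {sorted(incomplete)}"
        )
    pivot = ds.data.pivot(index="subject", columns="time", values="response")
    pivot = pivot.reindex(index=ds.subjects, columns=grid)
    group_of = ds.data.drop_duplicates("subject").set_index("subject")["group"]
    return WideMatrix(
        subjects=list(pivot.index),
        groups=group_of.loc[pivot.index].to_numpy(),
        times=grid,
        values=pivot.to_numpy(float),
    )


def complete_case_subset(ds: RepeatedMeasuresDataset) -> RepeatedMeasuresDataset:
    """Restrict to subjects measured at every time of the union grid.

    Returns a (possibly empty) dataset; logs how many subjects were kept
    and dropped.
    """
    m = ds.time_grid.size
    counts = ds.data.groupby("subject", sort=False)["time"].nunique()
    keep = counts.index[counts == m]
    dropped = counts.size - keep.size
    if keep.size == 0:
        logger.warning("no subject has complete measurements; empty subset")
    else:
        logger.info(
            "complete-case subset: %d subjects retained, %d dropped",
            keep.size,
            dropped,
        )
    sub = ds.data[ds.data["subject"].isin(keep)].reset_index(drop=True)
    return RepeatedMeasuresDataset(sub)
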