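"""Longitudinal survival data containers and delimited-text I/O.

The data model mirrors how longitudinal biomarker studies record follow-up:
each subject has an observed event-or-censoring time ``T``, an event indicator
``delta``, a vector of baseline (time-fixed) covariates, and a set of
longitudinal covariates measured on a discrete, subject-specific visit
schedule ``0 = t_1 < t_2 < ... < t_n = s <= T``.  The final observation time
``s`` is the last visit at which the biomarkers were measured; it never
exceeds the event time.  Between visits, trajectories are interpolated by
last-observation-carried-forward (LOCF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "Dataset",
    "Trajectory",
    "DataValidationError",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "locf_value",
]


class DataValidationError(ValueError):
    """Raised when a dataset violates the longitudinal-survival invariants."""


@dataclass
class Trajectory:
    """One covariate of one subject, piecewise-constant under LOCF.

    ``obs_times`` is strictly increasing with ``obs_times[0] == 0``; the
    trajectory is defined for every t >= 0: beyond the last observation the
    last value is carried forward indefinitely.
    """

    obs_times: np.ndarray
    values: np.ndarray
    interpolation: str = "locf"

    def __post_init__(self) -> None:
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.obs_times.ndim != 1 or self.obs_times.shape != self.values.shape:
            raise DataValidationError("obs_times and values must be 1-d and equal length")
        if len(self.obs_times) == 0:
            raise DataValidationError("trajectory needs at least one observation")
        if np.any(np.diff(self.obs_times) <= 0):
            raise DataValidationError("obs_times must be strictly increasing")

    def __call__(self, t: float) -> float:
        return locf_value(self, t)


def locf_value(traj: Trajectory, t: float) -> float:
    """Evaluate a trajectory at time ``t`` by last observation carried forward.

    The carried value is closed on the left: an observation exactly at ``t``
    belongs to the result (``max{t_l : t_l <= t}``).  For ``t`` beyond the
    final observation the last value is returned.
    """
    if t < traj.obs_times[0]:
        raise ValueError(
            f"LOCF undefined at t={t} before first observation {traj.obs_times[0]}"
        )
    idx = int(np.searchsorted(traj.obs_times, t, side="right")) - 1
    return float(traj.values[idx])


@dataclass
class SubjectRecord:
    """One individual: event time, indicator, visits and covariates.

    Attributes
    ----------
    id : str
        Unique subject label.
    event_time : float
        Observed time ``T = min(T*, C)`` (event or censoring), study units.
    event : int
        1 if the event was observed, 0 if censored.
    obs_times : ndarray, shape (n,)
        Visit times, strictly increasing, starting at 0.
    values : ndarray, shape (p, n)
        Longitudinal covariate measurements at the visit times.
    fixed : ndarray, shape (q,)
        Time-fixed covariates.
    """

    id: str
    event_time: float
    event: int
    obs_times: np.ndarray
    values: np.ndarray
    fixed: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.obs_times = np.atleast_1d(np.asarray(self.obs_times, dtype=float))
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.fixed = np.atleast_1d(np.asarray(self.fixed, dtype=float))
        self.event = int(self.event)
        self.event_time = float(self.event_time)

    @property
    def s(self) -> float:
        """Final observation time ``s = t_n``."""
        return float(self.obs_times[-1])

    @property
    def n_obs(self) -> int:
        return len(self.obs_times)

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return len(self.fixed)

    def trajectory(self, mu: int) -> Trajectory:
        """LOCF trajectory of longitudinal covariate ``mu``."""
        return Trajectory(self.obs_times, self.values[mu])

    def violations(self) -> list[str]:
        out = []
        if self.event not in (0, 1):
            out.append(f"subject {self.id}: event indicator must be 0 or 1")
        if self.event_time < 0:
            out.append(f"subject {self.id}: negative event time")
        if len(self.obs_times) == 0:
            out.append(f"subject {self.id}: no observations")
            return out
        if self.obs_times[0] != 0:
            out.append(f"subject {self.id}: first observation time must be 0")
        if np.any(np.diff(self.obs_times) <= 0):
            out.append(f"subject {self.id}: observation times not strictly increasing")
        if self.s > self.event_time:
            out.append(
                f"subject {self.id}: final observation time {self.s} exceeds "
                f"event time {self.event_time}"
            )
        if self.values.shape[1] != len(self.obs_times):
            out.append(f"subject {self.id}: covariate matrix does not match visit count")
        if not np.all(np.isfinite(self.values)):
            out.append(f"subject {self.id}: missing/non-finite longitudinal value")
        if not np.all(np.isfinite(self.fixed)):
            out.append(f"subject {self.id}: missing/non-finite fixed covariate")
        return out


@dataclass
class Dataset:
    """A cohort of :class:`SubjectRecord` with shared covariate layout."""

    subjects: list
    longitudinal_names: list
    fixed_names: list

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def p(self) -> int:
        return len(self.longitudinal_names)

    @property
    def q(self) -> int:
        return len(self.fixed_names)

    def __iter__(self):
        return iter(self.subjects)

    def __getitem__(self, i):
        return self.subjects[i]

    @property
    def event_times(self) -> np.ndarray:
        return np.array([s.event_time for s in self.subjects])

    @property
    def events(self) -> np.ndarray:
        return np.array([s.event for s in self.subjects])

    def subset(self, indices) -> "Dataset":
        return Dataset(
            [self.subjects[i] for i in indices],
            list(self.longitudinal_names),
            list(self.fixed_names),
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Export to (long table, subject table) DataFrames."""
        long_rows = []
        subj_rows = []
        for s in self.subjects:
            for j, t in enumerate(s.obs_times):
                row = {"id": s.id, "time": t}
                for mu, name in enumerate(self.longitudinal_names):
                    row[name] = s.values[mu, j]
                long_rows.append(row)
            srow = {"id": s.id, "event_time": s.event_time, "status": s.event}
            for nu, name in enumerate(self.fixed_names):
                srow[name] = s.fixed[nu]
            subj_rows.append(srow)
        return pd.DataFrame(long_rows), pd.DataFrame(subj_rows)


def validate_dataset(d: Dataset) -> list[str]:
    """Report every invariant violation; an empty list means the data is valid."""
    report: list[str] = []
    seen = set()
    for s in d.subjects:
        if s.id in seen:
            report.append(f"duplicate subject id {s.id}")
        seen.add(s.id)
        if s.p != d.p:
            report.append(f"subject {s.id}: expected {d.p} longitudinal covariates")
        if s.q != d.q:
            report.append(f"subject {s.id}: expected {d.q} fixed covariates")
        report.extend(s.violations())
    return report


def _check_numeric(df: pd.DataFrame, cols, table: str) -> None:
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "id"].iloc[0]
            raise DataValidationError(
                f"non-numeric or missing value in column '{c}' of {table} table "
                f"(subject {bad})"
            )
        df[c] = vals


def read_dataset(long_table_path, subject_table_path, sep: str = ",") -> Dataset:
    """Read a dataset from long-format and subject-level delimited text.

    The long table has columns ``id,time,<cov1>,...,<covp>`` (one row per
    visit); the subject table has ``id,event_time,status,<fix1>,...,<fixq>``
    with status 1 = event, 0 = censored.  The two tables must contain exactly
    the same subjects, and the result must satisfy every dataset invariant.
    """
    long_df = pd.read_csv(long_table_path, sep=sep, dtype={"id": str},
                          float_precision="round_trip")
    subj_df = pd.read_csv(subject_table_path, sep=sep, dtype={"id": str},
                          float_precision="round_trip")

    for col in ("id", "time"):
        if col not in long_df.columns:
            raise DataValidationError(f"long table missing required column '{col}'")
    for col in ("id", "event_time", "status"):
        if col not in subj_df.columns:
            raise DataValidationError(f"subject table missing required column '{col}'")
    if len(long_df) == 0:
        raise DataValidationError("no observations in long table")

    long_names = [c for c in long_df.columns if c not in ("id", "time")]
    fixed_names = [c for c in subj_df.columns if c not in ("id", "event_time", "status")]
    _check_numeric(long_df, ["time"] + long_names, "long")
    _check_numeric(subj_df, ["event_time", "status"] + fixed_names, "subject")

    if subj_df["id"].duplicated().any():
        dup = subj_df.loc[subj_df["id"].duplicated(), "id"].iloc[0]
        raise DataValidationError(f"duplicate subject id {dup} in subject table")
    if long_df.duplicated(subset=["id", "time"]).any():
        dup = long_df.loc[long_df.duplicated(subset=["id", "time"]), "id"].iloc[0]
        raise DataValidationError(f"duplicate (id, time) row for subject {dup}")

    long_ids = set(long_df["id"])
    subj_ids = set(subj_df["id"])
    if long_ids - subj_ids:
        raise DataValidationError(
            f"subjects {sorted(long_ids - subj_ids)} in long table but not subject table"
        )
    if subj_ids - long_ids:
        raise DataValidationError(
            f"subjects {sorted(subj_ids - long_ids)} have no longitudinal observations"
        )

    subjects = []
    grouped = dict(tuple(long_df.groupby("id", sort=False)))
    for _, row in subj_df.iterrows():
        g = grouped[row["id"]].sort_values("time")
        subjects.append(
            SubjectRecord(
                id=row["id"],
                event_time=row["event_time"],
                event=int(row["status"]),
                obs_times=g["time"].to_numpy(),
                values=g[long_names].to_numpy().T,
                fixed=row[fixed_names].to_numpy(dtype=float),
            )
        )
    d = Dataset(subjects, long_names, fixed_names)
    report = validate_dataset(d)
    if report:
        raise DataValidationError("; ".join(report))
    return d


def write_dataset(d: Dataset, long_table_path, subject_table_path, sep: str = ",") -> None:
    """Write the long and subject tables read back by :func:`read_dataset`."""
    long_df, subj_df = d.to_frames()
    # repr-round-trip precision so writer -> reader reproduces floats exactly
    long_df.to_csv(long_table_path, sep=sep, index=False, float_format="%.17g")
    subj_df.to_csv(subject_table_path, sep=sep, index=False, float_format="%.17g")
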