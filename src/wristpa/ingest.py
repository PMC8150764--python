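"""Reading and validating raw recordings, annotations and participant rosters.

Raw recordings are columnar CSV with header ``timestamp,x,y,z``: timestamp in
seconds from recording start (an ISO-8601 reader option exists), acceleration
in g. Supported native sampling rates are 30, 80 and 100 Hz and no resampling
is ever performed — feature extraction operates at the native rate.

The module also implements the cohort accounting used for the study-style
exclusion cascade: participants missing activity start/end times, with
insufficient activity data, or with missing demographics are excluded (in
that order of precedence); energy-expenditure modelling additionally requires
a valid-calorimetry flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, InputError, RateError

SUPPORTED_RATES_HZ = (30, 80, 100)

#: Exclusion flags checked in order; the first failing flag is the reason.
EXCLUSION_ORDER = (
    ("has_start_end_times", "missing start/end time of activities"),
    ("has_sufficient_activity_data", "insufficient length of activity or missing values"),
    ("has_demographics", "missing demographic information"),
)

ROSTER_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "has_start_end_times",
    "has_sufficient_activity_data",
    "has_demographics",
    "has_valid_ee",
    "visits_attended",
]

ANNOTATION_COLUMNS = [
    "participant_id",
    "visit_id",
    "activity_name",
    "start_s",
    "end_s",
    "met",
]


@dataclass
class RawRecording:
    """One participant-visit tri-axial signal at its native sampling rate."""

    participant_id: str
    visit_id: str
    rate_hz: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise FormatError("channels must have equal length")
        if self.rate_hz not in SUPPORTED_RATES_HZ:
            raise RateError(f"unsupported sampling rate {self.rate_hz} Hz")
        if n > 1:
            dt = np.diff(self.t)
            if not np.all(dt > 0):
                raise FormatError("timestamps must be strictly increasing")
            median_dt = float(np.median(dt))
            if abs(median_dt * self.rate_hz - 1.0) > 0.01:
                raise RateError(
                    f"declared rate {self.rate_hz} Hz inconsistent with "
                    f"median spacing {median_dt:.6g} s"
                )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        if self.n_samples == 0:
            return 0.0
        return float(self.t[-1] - self.t[0]) + 1.0 / self.rate_hz

    def data(self) -> np.ndarray:
        """Samples as an (n, 3) array."""
        return np.column_stack([self.x, self.y, self.z])


def read_raw_recording(
    path,
    declared_rate_hz: int,
    participant_id: str | None = None,
    visit_id: str | None = None,
    timestamp_format: str = "seconds",
) -> RawRecording:
    """Read a raw-recording CSV and validate it against the declared rate.

    ``timestamp_format="iso8601"`` parses absolute timestamps and converts to
    seconds from the first sample. Monotonicity and a 1% rate-consistency
    check on median sample spacing are enforced; no resampling is performed.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"timestamp", "x", "y", "z"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if timestamp_format == "iso8601":
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
        t = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    elif timestamp_format == "seconds":
        t = df["timestamp"].to_numpy(dtype=float)
    else:
        raise InputError(f"unknown timestamp_format {timestamp_format!r}")
    if participant_id is None or visit_id is None:
        # canonical file naming: <participant>_<visit>.csv
        stem_parts = path.stem.split("_")
        participant_id = participant_id or stem_parts[0]
        visit_id = visit_id or (stem_parts[1] if len(stem_parts) > 1 else "V1")
    return RawRecording(
        participant_id=participant_id,
        visit_id=visit_id,
        rate_hz=int(declared_rate_hz),
        t=t,
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        z=df["z"].to_numpy(dtype=float),
    )


def write_raw_recording(recording: RawRecording, path) -> None:
    """Write a recording in the canonical CSV dialect (lossless round trip)."""
    # shortest round-trip float repr; pandas' to_csv truncates precision
    with open(path, "w") as fh:
        fh.write("timestamp,x,y,z\n")
        for row in zip(recording.t, recording.x, recording.y, recording.z):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if not (df["end_s"] > df["start_s"]).all():
        raise FormatError("every interval must satisfy end_s > start_s")
    return df[ANNOTATION_COLUMNS]


def read_roster(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ROSTER_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return validate_roster(df[ROSTER_COLUMNS])


def validate_roster(roster: pd.DataFrame) -> pd.DataFrame:
    roster = roster.copy()
    for col in (
        "has_start_end_times",
        "has_sufficient_activity_data",
        "has_demographics",
        "has_valid_ee",
    ):
        roster[col] = roster[col].astype(bool)
    if len(roster):
        ages = roster["age"].to_numpy(dtype=float)
        if ages.min() < 20 or ages.max() > 89:
            raise InputError("ages must lie in [20, 89]")
        visits = roster["visits_attended"].to_numpy()
        if not np.isin(visits, [1, 2, 3, 4]).all():
            raise InputError("visits_attended must be in {1, 2, 3, 4}")
    return roster


def apply_exclusions(roster: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a roster into included and excluded participants.

    A participant is excluded iff any of the three data-completeness flags is
    false; the first failing flag (start/end times, sufficient data,
    demographics) is recorded as the exclusion reason, so reasons are
    mutually exclusive counts.

    Returns
    -------
    (included, excluded) : tuple of DataFrames
        ``excluded`` carries an extra ``exclusion_reason`` column.
    """
    if len(roster) == 0:
        empty = roster.copy()
        excluded = roster.copy()
        excluded["exclusion_reason"] = pd.Series(dtype=object)
        return empty, excluded
    reasons = pd.Series(index=roster.index, dtype=object)
    for flag, reason in EXCLUSION_ORDER:
        failing = ~roster[flag].astype(bool) & reasons.isna()
        reasons[failing] = reason
    excluded = roster[reasons.notna()].copy()
    excluded["exclusion_reason"] = reasons[reasons.notna()]
    included = roster[reasons.isna()].copy()
    return included, excluded


def ee_eligible(included: pd.DataFrame) -> pd.DataFrame:
    """Retain participants with valid energy-expenditure (calorimetry) data."""
    if len(included) == 0:
        return included.copy()
    return included[included["has_valid_ee"].astype(bool)].copy()


def count_visits(roster: pd.DataFrame) -> int:
    """Total data-collection visits: the sum of per-participant attendance."""
    if len(roster) == 0:
        return 0
    return int(roster["visits_attended"].sum())
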