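"""Labels: METs from calorimetry, intensity classes, activity types, age
groups, and assembly of the four task datasets.

Energy cost is expressed in METs (= VO2 / 3.5 mL·min⁻¹·kg⁻¹). Intensity is a
three-level step function of the MET value (low / light / moderate) with
configurable cutoffs; the defaults, 1.5 and 3.0 METs, are the conventional
sedentary-light and light-moderate boundaries. Activity type (sedentary /
locomotion / lifestyle) is a configurable mapping over the activity catalog;
the four strength/stretching activities map to ``none`` and are removed from
type-recognition tasks. Age groups are young [20, 50], middle (50, 70],
old (70, 89].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import PA_TYPES, default_type_mapping
from .exceptions import EmptyDatasetError, InputError
from .features import FEATURE_NAMES

VO2_PER_MET = 3.5  # mL·min^-1·kg^-1 per MET

AGE_GROUPS = ("young", "middle", "old")
TASK_KINDS = (
    "type_binary",
    "intensity_binary",
    "individual_multiclass",
    "ee_regression",
    "type_multiclass",
)
TYPE_TARGETS = ("sedentary", "locomotion", "lifestyle")
INTENSITY_TARGETS = ("low", "light", "moderate")


@dataclass(frozen=True)
class IntensityScheme:
    """MET cutoffs: low iff met <= low_max; light iff met <= light_max."""

    low_max: float = 1.5
    light_max: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.low_max < self.light_max:
            raise InputError("require 0 < low_max < light_max")


def smooth_vo2(times: np.ndarray, values: np.ndarray, window_s: float = 30.0) -> np.ndarray:
    """Centred running average of a breath-by-breath VO2 series.

    Each output sample is the mean over ``[t - window_s/2, t + window_s/2]``
    (inclusive); at the series edges the available partial window is used.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) == 0:
        raise InputError("empty series")
    if len(times) != len(values):
        raise InputError("times and values must align")
    if np.any(np.diff(times) <= 0):
        raise InputError("timestamps must be strictly increasing")
    half = window_s / 2.0
    lo = np.searchsorted(times, times - half, side="left")
    hi = np.searchsorted(times, times + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def steady_state_vo2(
    times: np.ndarray, values: np.ndarray, start_s: float, end_s: float
) -> float:
    """Mean smoothed VO2 over a chosen steady-state sub-interval.

    Plateau choice is supplied by the caller (``start_s``/``end_s``); this
    helper replaces expert visual plateau identification with a reproducible
    interval mean.
    """
    times = np.asarray(times, dtype=float)
    if end_s <= start_s:
        raise InputError("end_s must exceed start_s")
    smoothed = smooth_vo2(times, values)
    mask = (times >= start_s) & (times <= end_s)
    if not mask.any():
        raise InputError("no samples in the steady-state interval")
    return float(np.mean(smoothed[mask]))


def met_from_vo2(vo2) -> float | np.ndarray:
    """Convert mass-normalised VO2 (mL·min⁻¹·kg⁻¹) to METs (VO2 / 3.5)."""
    vo2 = np.asarray(vo2, dtype=float)
    if np.any(vo2 < 0):
        raise InputError("VO2 must be nonnegative")
    met = vo2 / VO2_PER_MET
    return float(met) if met.ndim == 0 else met


def intensity_from_met(met: float, scheme: IntensityScheme | None = None) -> str:
    """Map a MET value to low / light / moderate under the scheme's cutoffs."""
    scheme = scheme or IntensityScheme()
    if not met > 0:
        raise InputError("met must be positive")
    if met <= scheme.low_max:
        return "low"
    if met <= scheme.light_max:
        return "light"
    return "moderate"


def assign_age_group(age: float) -> str:
    """Age group: young [20, 50], middle (50, 70], old (70, 89]."""
    if not 20 <= age <= 89:
        raise InputError(f"age {age} outside [20, 89]")
    if age <= 50:
        return "young"
    if age <= 70:
        return "middle"
    return "old"


def validate_type_mapping(mapping: dict[str, str], catalog_names) -> dict[str, str]:
    missing = set(catalog_names) - set(mapping)
    if missing:
        raise InputError(f"type mapping missing activities: {sorted(missing)}")
    bad = {v for v in mapping.values() if v not in PA_TYPES}
    if bad:
        raise InputError(f"unknown pa types in mapping: {sorted(bad)}")
    return mapping


def load_label_config(path) -> tuple[dict[str, str], IntensityScheme]:
    """Read a YAML config holding ``type_mapping`` and ``intensity_cutoffs``."""
    with open(Path(path)) as fh:
        cfg = yaml.safe_load(fh)
    mapping = dict(cfg.get("type_mapping") or default_type_mapping())
    cuts = cfg.get("intensity_cutoffs") or {}
    scheme = IntensityScheme(
        low_max=float(cuts.get("low_max", 1.5)), light_max=float(cuts.get("light_max", 3.0))
    )
    return mapping, scheme


@dataclass
class TaskDataset:
    """Aligned features, targets and participant grouping for one task."""

    kind: str
    target_name: str | None
    age_stratum: str
    X: pd.DataFrame  # n_windows x 49, canonical column order
    y: np.ndarray
    groups: np.ndarray  # participant id per row

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise InputError("X, y and groups must align")
        if list(self.X.columns) != FEATURE_NAMES:
            raise InputError("X must carry the 49 features in canonical order")

    @property
    def n_windows(self) -> int:
        return len(self.X)

    @property
    def n_participants(self) -> int:
        return len(np.unique(self.groups))

    @property
    def is_regression(self) -> bool:
        return self.kind == "ee_regression"


def negative_label(target_name: str) -> str:
    return f"non_{target_name}"


def build_task_dataset(
    windows: pd.DataFrame,
    roster: pd.DataFrame,
    kind: str,
    target_name: str | None = None,
    age_stratum: str = "all",
    mapping: dict[str, str] | None = None,
    scheme: IntensityScheme | None = None,
) -> TaskDataset:
    """Assemble one task dataset from the window feature table and roster.

    * ``type_binary``: windows of type-``none`` activities are dropped;
      y is ``target_name`` vs ``non_<target_name>`` by the type mapping.
    * ``intensity_binary``: y from the MET value under the intensity scheme.
    * ``individual_multiclass``: y is the activity name (all 33 classes).
    * ``ee_regression``: y is the MET value; rows restricted to participants
      with valid calorimetry.
    * ``type_multiclass``: 3-class variant of the type task (used for
      separability diagnostics).
    """
    if kind not in TASK_KINDS:
        raise InputError(f"unknown task kind {kind!r}")
    mapping = mapping or default_type_mapping()
    scheme = scheme or IntensityScheme()
    df = windows.merge(
        roster[["participant_id", "age", "has_valid_ee"]], on="participant_id", how="inner"
    )
    if age_stratum != "all":
        if age_stratum not in AGE_GROUPS:
            raise InputError(f"unknown age stratum {age_stratum!r}")
        groups = df["age"].map(assign_age_group)
        df = df[groups == age_stratum]

    if kind in ("type_binary", "type_multiclass"):
        validate_type_mapping(mapping, df["activity_name"].unique())
        types = df["activity_name"].map(mapping)
        df = df[types != "none"]
        types = types[types != "none"]
        if kind == "type_binary":
            if target_name not in TYPE_TARGETS:
                raise InputError(f"unknown type target {target_name!r}")
            y = np.where(types == target_name, target_name, negative_label(target_name))
        else:
            y = types.to_numpy()
    elif kind == "intensity_binary":
        if target_name not in INTENSITY_TARGETS:
            raise InputError(f"unknown intensity target {target_name!r}")
        intensities = df["met"].map(lambda m: intensity_from_met(m, scheme))
        y = np.where(intensities == target_name, target_name, negative_label(target_name))
    elif kind == "individual_multiclass":
        y = df["activity_name"].to_numpy()
    elif kind == "ee_regression":
        df = df[df["has_valid_ee"].astype(bool)]
        y = df["met"].to_numpy(dtype=float)
        if np.any(~(y > 0)):
            raise InputError("regression targets must be positive METs")
    if len(df) == 0:
        raise EmptyDatasetError(
            f"no windows for kind={kind}, target={target_name}, stratum={age_stratum}"
        )
    return TaskDataset(
        kind=kind,
        target_name=target_name,
        age_stratum=age_stratum,
        X=df[FEATURE_NAMES].reset_index(drop=True),
        y=np.asarray(y),
        groups=df["participant_id"].to_numpy(),
    )
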