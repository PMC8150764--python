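"""Synthetic wrist-accelerometry cohort generator.

The study-style corpus this package analyses (scripted daily activities with
simultaneous indirect calorimetry) is not publicly deposited, so this module
generates labelled recordings with the statistical structure the pipeline
assumes: per activity, a static gravity orientation plus a single sinusoid at
the activity's dominant frequency (random phase per interval) plus i.i.d.
Gaussian sensor noise, and a steady-state MET value drawn per
participant-activity from a truncated normal. Every downstream stage — ingest,
windowing, feature extraction, task assembly, nested cross-validation — runs
on this output with no external data.

The signal model is deliberately minimal: it is the simplest generator that
makes the amplitude, orientation and spectral features informative. It makes
no claim of biomechanical realism (no gait harmonics, autocorrelated noise,
non-wear or orientation drift).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .catalog import ActivityProfile, default_catalog
from .exceptions import InputError
from .ingest import SUPPORTED_RATES_HZ, RawRecording, write_raw_recording

AGE_BINS = {"young": (20.0, 50.0), "middle": (50.0, 70.0), "old": (70.0, 89.0)}

MET_TRUNCATION = 0.1  # METs; floor on generated energy expenditure


@dataclass
class SyntheticCohortConfig:
    """Configuration of a synthetic cohort.

    Defaults mirror the scripted-protocol setting: all participants perform
    every catalog activity for ~8 min at the device's native 100 Hz rate, in
    one visit, ordered from lowest to highest metabolic demand. Group sizes
    default to a desk-scale cohort of 5 participants per age group.
    """

    n_young: int = 5
    n_middle: int = 5
    n_old: int = 5
    rate_hz: int = 100
    duration_s: float = 480.0
    activity_catalog: list[ActivityProfile] = field(default_factory=default_catalog)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz not in SUPPORTED_RATES_HZ:
            raise InputError(f"unsupported sampling rate {self.rate_hz} Hz")
        if min(self.n_young, self.n_middle, self.n_old) < 0:
            raise InputError("group sizes must be nonnegative")
        if not self.activity_catalog:
            raise InputError("activity catalog must be non-empty")
        if self.duration_s < 60:
            raise InputError("duration_s must allow at least one 60-s window")

    @property
    def n_participants(self) -> int:
        return self.n_young + self.n_middle + self.n_old


@dataclass
class Cohort:
    """Roster, recordings and activity intervals of one generated cohort."""

    roster: pd.DataFrame
    recordings: list[RawRecording]
    intervals: pd.DataFrame
    config: SyntheticCohortConfig


def generate_activity_signal(
    profile: ActivityProfile,
    duration_s: float,
    rate_hz: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate one activity's tri-axial signal as an (n, 3) array in g.

    Per axis: ``gravity + amp * sin(2*pi*f*t + phase) + noise`` with one
    uniform random phase per axis per call and i.i.d. Gaussian noise.
    """
    if duration_s <= 0:
        raise InputError("duration_s must be positive")
    if rate_hz not in SUPPORTED_RATES_HZ:
        raise InputError(f"unsupported sampling rate {rate_hz} Hz")
    if not profile.dom_freq_hz < rate_hz / 2:
        raise InputError(
            f"dom_freq_hz {profile.dom_freq_hz} must be below Nyquist ({rate_hz / 2} Hz)"
        )
    n = round(duration_s * rate_hz)
    t = np.arange(n) / rate_hz
    phases = rng.uniform(0.0, 2.0 * math.pi, size=3)
    out = np.empty((n, 3))
    for axis in range(3):
        out[:, axis] = profile.gravity_axis[axis] + profile.amp_g[axis] * np.sin(
            2.0 * math.pi * profile.dom_freq_hz * t + phases[axis]
        )
    if profile.noise_sd_g > 0:
        out += rng.normal(0.0, profile.noise_sd_g, size=(n, 3))
    return out


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Generate a full cohort: roster, one recording per participant, intervals.

    Participant ages are uniform within their group's bin; each participant
    performs every catalog activity once (ordered by MET mean, emulating the
    low-to-high metabolic ordering of the protocol) in a single visit. The
    interval MET is drawn Normal(met_mean, met_sd), truncated below at
    0.1 MET. Output is byte-identical for identical (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    catalog = sorted(config.activity_catalog, key=lambda p: p.met_mean)
    rows, recordings, intervals = [], [], []
    pid_counter = 0
    for group in ("young", "middle", "old"):
        lo, hi = AGE_BINS[group]
        n_group = {"young": config.n_young, "middle": config.n_middle, "old": config.n_old}[group]
        for _ in range(n_group):
            pid_counter += 1
            pid = f"P{pid_counter:03d}"
            age = float(rng.uniform(lo, hi))
            sex = "F" if rng.uniform() < 0.62 else "M"
            rows.append(
                {
                    "participant_id": pid,
                    "age": round(age, 1),
                    "sex": sex,
                    "has_start_end_times": True,
                    "has_sufficient_activity_data": True,
                    "has_demographics": True,
                    "has_valid_ee": True,
                    "visits_attended": 1,
                }
            )
            segments = []
            offset = 0.0
            for profile in catalog:
                sig = generate_activity_signal(profile, config.duration_s, config.rate_hz, rng)
                met = max(MET_TRUNCATION, float(rng.normal(profile.met_mean, profile.met_sd)))
                intervals.append(
                    {
                        "participant_id": pid,
                        "visit_id": "V1",
                        "activity_name": profile.name,
                        "start_s": offset,
                        "end_s": offset + len(sig) / config.rate_hz,
                        "met": met,
                    }
                )
                segments.append(sig)
                offset += len(sig) / config.rate_hz
            data = np.vstack(segments)
            t = np.arange(len(data)) / config.rate_hz
            recordings.append(
                RawRecording(
                    participant_id=pid,
                    visit_id="V1",
                    rate_hz=config.rate_hz,
                    t=t,
                    x=data[:, 0],
                    y=data[:, 1],
                    z=data[:, 2],
                )
            )
    roster = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "age",
            "sex",
            "has_start_end_times",
            "has_sufficient_activity_data",
            "has_demographics",
            "has_valid_ee",
            "visits_attended",
        ],
    )
    intervals_df = pd.DataFrame(intervals)
    return Cohort(roster=roster, recordings=recordings, intervals=intervals_df, config=config)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Materialise a cohort in the canonical on-disk layout.

    ``raw/<participant>_<visit>.csv`` recordings, ``annotations.csv``,
    ``roster.csv`` and a ``metadata.yaml`` recording the seed and generator
    settings.
    """
    from pathlib import Path

    out = Path(out_dir)
    (out / "raw").mkdir(parents=True, exist_ok=True)
    for rec in cohort.recordings:
        write_raw_recording(rec, out / "raw" / f"{rec.participant_id}_{rec.visit_id}.csv")
    cohort.intervals.to_csv(out / "annotations.csv", index=False)
    cohort.roster.to_csv(out / "roster.csv", index=False)
    cfg = cohort.config
    meta = {
        "seed": cfg.seed,
        "rate_hz": cfg.rate_hz,
        "duration_s": cfg.duration_s,
        "n_young": cfg.n_young,
        "n_middle": cfg.n_middle,
        "n_old": cfg.n_old,
        "n_activities": len(cfg.activity_catalog),
        "activities": [p.name for p in cfg.activity_catalog],
    }
    with open(out / "metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def accounting_roster() -> pd.DataFrame:
    """Synthetic roster reproducing the study-style cohort accounting.

    264 enrolled participants: 6 missing activity start/end times, 3 with
    insufficient activity data, 2 missing demographics (so 253 analysable);
    6 of the included lack valid calorimetry (247 EE-eligible). Visit
    attendance among the included is 213/21/7/12 participants attending
    4/3/2/1 visits. Ages and sexes are deterministic filler — this fixture
    exists for exclusion/visit accounting, not signal analysis.
    """
    rng = np.random.default_rng(264)
    n = 264
    ages = np.round(rng.uniform(20, 89, size=n), 1)
    df = pd.DataFrame(
        {
            "participant_id": [f"S{i:03d}" for i in range(1, n + 1)],
            "age": ages,
            "sex": np.where(rng.uniform(size=n) < 0.62, "F", "M"),
            "has_start_end_times": True,
            "has_sufficient_activity_data": True,
            "has_demographics": True,
            "has_valid_ee": True,
            "visits_attended": 4,
        }
    )
    df.loc[0:5, "has_start_end_times"] = False  # 6 participants
    df.loc[6:8, "has_sufficient_activity_data"] = False  # 3 participants
    df.loc[9:10, "has_demographics"] = False  # 2 participants
    included_idx = df.index[11:]  # 253 participants
    df.loc[included_idx[:6], "has_valid_ee"] = False  # 247 EE-eligible
    # attendance multiplicities among the included: 213*4 + 21*3 + 7*2 + 12*1 = 941
    attendance = np.concatenate([np.repeat(4, 213), np.repeat(3, 21), np.repeat(2, 7), np.repeat(1, 12)])
    df.loc[included_idx, "visits_attended"] = attendance
    return df
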