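"""Windowing and the 49 time/frequency-domain wrist features.

Recordings are cut into consecutive, non-overlapping 60-s windows anchored at
each annotated activity interval's start (trailing partial data is dropped),
and each window is summarised by 46 time-domain and 3 frequency-domain
features of the tri-axial signal and its vector magnitude (VM):

* ``mvm``/``sdvm``: mean and sd of VM; ``mangle``/``sdangle``: mean and sd of
  the angle between the x axis and the VM vector, in degrees,
  ``asin(x / vm)``;
* per-axis mean, sd and coefficient of variation (``100 * sd / |mean|``);
* min, max, 25% and 75% quantiles of VM and each axis;
* third and fourth central moments, skewness and kurtosis of VM and each
  axis; ``cv_vm`` (``100 * sdvm / mvm``);
* spectral features of VM with the DC bin excluded: ``p625`` (fraction of
  spectral modulus in 0.6–2.5 Hz, the human-movement band), ``df`` (dominant
  frequency) and ``fpdf`` (the dominant bin's share of total modulus).

Conventions (frozen for reproducibility): sd is the n-1 sample estimator;
quantiles interpolate linearly between order statistics; third/fourth moments
are population central moments, skewness = m3/m2^1.5 and kurtosis = m4/m2^2
(non-excess), both 0 for a constant signal; CV is 0 when |mean| < 1e-6 g; on
ties the dominant frequency is the lowest tied bin; an all-zero spectrum
yields (0, 0, 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError
from .ingest import RawRecording

logger = logging.getLogger(__name__)

WINDOW_S = 60

_CHANNELS = ("vm", "x", "y", "z")

#: Canonical order of the 49 features; fixed across sampling rates.
FEATURE_NAMES: list[str] = (
    ["mvm", "sdvm", "mangle", "sdangle"]
    + [f"mean_{a}" for a in "xyz"]
    + [f"sd_{a}" for a in "xyz"]
    + [f"cv_{a}" for a in "xyz"]
    + [f"min_{c}" for c in _CHANNELS]
    + [f"max_{c}" for c in _CHANNELS]
    + [f"lower_{c}_25" for c in _CHANNELS]
    + [f"upper_{c}_75" for c in _CHANNELS]
    + [f"third_moment_{c}" for c in _CHANNELS]
    + [f"fourth_moment_{c}" for c in _CHANNELS]
    + [f"skewness_{c}" for c in _CHANNELS]
    + [f"kurtosis_{c}" for c in _CHANNELS]
    + ["cv_vm", "p625", "df", "fpdf"]
)

TIME_FEATURE_NAMES: list[str] = FEATURE_NAMES[:46]
FREQ_FEATURE_NAMES: list[str] = FEATURE_NAMES[46:]

_CV_MEAN_GUARD = 1e-6  # g; below this the CV is reported as 0
_VAR_GUARD = 1e-24  # g^2; below this skewness/kurtosis are reported as 0


@dataclass
class WindowSlice:
    """One complete 60-s raw window with its labels."""

    participant_id: str
    visit_id: str
    activity_name: str
    window_index: int
    rate_hz: int
    met: float
    data: np.ndarray  # (n, 3)


def segment_windows(
    recording: RawRecording,
    intervals: pd.DataFrame,
    window_s: float = WINDOW_S,
) -> list[WindowSlice]:
    """Cut a recording into non-overlapping windows, one list per interval.

    Windows are anchored at the interval start; ``floor(length / window_s)``
    complete windows are produced and trailing partial data discarded.
    """
    slices: list[WindowSlice] = []
    n_win_samples = round(window_s * recording.rate_hz)
    for row in intervals.itertuples(index=False):
        if row.participant_id != recording.participant_id or row.visit_id != recording.visit_id:
            continue
        if row.start_s < recording.t[0] - 0.5 / recording.rate_hz or row.end_s > recording.t[
            -1
        ] + 1.5 / recording.rate_hz:
            raise InputError(
                f"interval [{row.start_s}, {row.end_s}] s outside recording "
                f"{recording.participant_id}/{recording.visit_id}"
            )
        i0 = int(np.searchsorted(recording.t, row.start_s - 0.5 / recording.rate_hz, side="left"))
        i1 = int(np.searchsorted(recording.t, row.end_s - 0.5 / recording.rate_hz, side="left"))
        n_windows = (i1 - i0) // n_win_samples
        data = recording.data()
        for w in range(n_windows):
            a = i0 + w * n_win_samples
            slices.append(
                WindowSlice(
                    participant_id=recording.participant_id,
                    visit_id=recording.visit_id,
                    activity_name=row.activity_name,
                    window_index=w,
                    rate_hz=recording.rate_hz,
                    met=float(row.met) if row.met == row.met else float("nan"),
                    data=data[a : a + n_win_samples],
                )
            )
    return slices


def vector_magnitude(x, y, z) -> np.ndarray:
    """Per-sample Euclidean norm of the three axes, in g."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if not (len(x) == len(y) == len(z)):
        raise InputError("axes must have equal length")
    return np.sqrt(x * x + y * y + z * z)


def angle_to_vertical(x, vm) -> np.ndarray:
    """Angle between the x axis and the VM vector, degrees; 0 where VM = 0."""
    x = np.asarray(x, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if len(x) != len(vm):
        raise InputError("x and vm must have equal length")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(vm > 0, x / np.where(vm > 0, vm, 1.0), 0.0)
    return np.degrees(np.arcsin(np.clip(ratio, -1.0, 1.0)))


def _sample_sd(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0


def _cv(sd: float, mean: float) -> float:
    if abs(mean) < _CV_MEAN_GUARD:
        logger.warning("CV guard triggered: |mean| < %.0e g, reporting CV = 0", _CV_MEAN_GUARD)
        return 0.0
    return 100.0 * sd / abs(mean)


def _channel_stats(v: np.ndarray) -> dict[str, float]:
    mean = float(np.mean(v))
    centred = v - mean
    m2 = float(np.mean(centred**2))
    m3 = float(np.mean(centred**3))
    m4 = float(np.mean(centred**4))
    if m2 < _VAR_GUARD:
        skew = kurt = 0.0
    else:
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    q25, q75 = np.quantile(v, [0.25, 0.75])
    return {
        "mean": mean,
        "sd": _sample_sd(v),
        "min": float(np.min(v)),
        "max": float(np.max(v)),
        "q25": float(q25),
        "q75": float(q75),
        "m3": m3,
        "m4": m4,
        "skew": skew,
        "kurt": kurt,
    }


def extract_time_features(data: np.ndarray, rate_hz: int | None = None) -> dict[str, float]:
    """Compute the 46 time-domain features of one window.

    ``data`` is an (n, 3) array; if ``rate_hz`` is given the window must hold
    exactly ``round(60 * rate_hz)`` samples.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 3:
        raise InputError("window must be an (n, 3) array")
    if rate_hz is not None and data.shape[0] != round(WINDOW_S * rate_hz):
        raise InputError(
            f"incomplete window: {data.shape[0]} samples, expected {round(WINDOW_S * rate_hz)}"
        )
    x, y, z = data[:, 0], data[:, 1], data[:, 2]
    vm = vector_magnitude(x, y, z)
    angle = angle_to_vertical(x, vm)
    stats = {"vm": _channel_stats(vm), "x": _channel_stats(x), "y": _channel_stats(y), "z": _channel_stats(z)}
    out: dict[str, float] = {
        "mvm": stats["vm"]["mean"],
        "sdvm": stats["vm"]["sd"],
        "mangle": float(np.mean(angle)),
        "sdangle": _sample_sd(angle),
    }
    for a in "xyz":
        out[f"mean_{a}"] = stats[a]["mean"]
    for a in "xyz":
        out[f"sd_{a}"] = stats[a]["sd"]
    for a in "xyz":
        out[f"cv_{a}"] = _cv(stats[a]["sd"], stats[a]["mean"])
    for key, stat in (("min", "min"), ("max", "max")):
        for c in _CHANNELS:
            out[f"{key}_{c}"] = stats[c][stat]
    for c in _CHANNELS:
        out[f"lower_{c}_25"] = stats[c]["q25"]
    for c in _CHANNELS:
        out[f"upper_{c}_75"] = stats[c]["q75"]
    for c in _CHANNELS:
        out[f"third_moment_{c}"] = stats[c]["m3"]
    for c in _CHANNELS:
        out[f"fourth_moment_{c}"] = stats[c]["m4"]
    for c in _CHANNELS:
        out[f"skewness_{c}"] = stats[c]["skew"]
    for c in _CHANNELS:
        out[f"kurtosis_{c}"] = stats[c]["kurt"]
    out["cv_vm"] = _cv(stats["vm"]["sd"], stats["vm"]["mean"])
    return {name: out[name] for name in TIME_FEATURE_NAMES}


def extract_freq_features(vm: np.ndarray, rate_hz: int) -> dict[str, float]:
    """Spectral features (p625, df, fpdf) of one window's VM series.

    Uses the discrete Fourier transform of the full 60-s VM series with the
    DC bin excluded; frequency bins are k/60 Hz for k = 1..floor(N/2).
    """
    vm = np.asarray(vm, dtype=float)
    n = round(WINDOW_S * rate_hz)
    if len(vm) != n:
        raise InputError(f"incomplete window: {len(vm)} samples, expected {n}")
    moduli = np.abs(np.fft.rfft(vm))[1:]  # k = 1 .. floor(N/2)
    freqs = np.arange(1, len(moduli) + 1) / WINDOW_S
    total = float(moduli.sum())
    if total <= 1e-12:
        return {"p625": 0.0, "df": 0.0, "fpdf": 0.0}
    band = (freqs >= 0.6 - 1e-9) & (freqs <= 2.5 + 1e-9)
    k_dom = int(np.argmax(moduli))  # argmax takes the lowest tied bin
    return {
        "p625": float(moduli[band].sum() / total),
        "df": float(freqs[k_dom]),
        "fpdf": float(moduli[k_dom] / total),
    }


def extract_features(data: np.ndarray, rate_hz: int) -> dict[str, float]:
    """All 49 features of one complete window, in canonical order."""
    time_feats = extract_time_features(data, rate_hz=rate_hz)
    vm = vector_magnitude(data[:, 0], data[:, 1], data[:, 2])
    freq_feats = extract_freq_features(vm, rate_hz)
    out = {**time_feats, **freq_feats}
    assert list(out) == FEATURE_NAMES
    return out


def windows_to_table(slices: list[WindowSlice]) -> pd.DataFrame:
    """Feature table: id/label columns followed by the 49 feature columns."""
    rows = []
    for s in slices:
        row = {
            "participant_id": s.participant_id,
            "visit_id": s.visit_id,
            "activity_name": s.activity_name,
            "window_index": s.window_index,
            "rate_hz": s.rate_hz,
            "met": s.met,
        }
        row.update(extract_features(s.data, s.rate_hz))
        rows.append(row)
    return pd.DataFrame(rows)


def extract_cohort_features(
    recordings: list[RawRecording], intervals: pd.DataFrame
) -> pd.DataFrame:
    """Segment every recording and assemble the cohort feature table."""
    slices: list[WindowSlice] = []
    for rec in recordings:
        slices.extend(segment_windows(rec, intervals))
    if not slices:
        raise InputError("no complete windows produced")
    return windows_to_table(slices)
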