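"""Default 33-activity catalog for the synthetic cohort generator.

Each activity is described by an :class:`ActivityProfile`: a static gravity
orientation of the wrist, a single dominant oscillation (frequency and
per-axis amplitude), white sensor noise, and a steady-state metabolic cost
(MET mean and between-participant sd). Profiles are grouped into the three
physical-activity types used downstream (sedentary, locomotion, lifestyle);
the three strength exercises and stretching yoga carry type ``none`` and are
dropped from type-recognition tasks.

The MET means, frequencies, amplitudes and orientations are package defaults
chosen so that (a) each activity's MET distribution lies well inside one
intensity band under the default 1.5/3.0 MET cutoffs, and (b) the three types
occupy distinct regions of orientation/frequency/amplitude space so the
pipeline's separability properties are testable. They are configuration, not
measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError

PA_TYPES = ("sedentary", "locomotion", "lifestyle", "none")

#: Activities that do not fit the sedentary/locomotion/lifestyle scheme.
TYPE_EXCLUDED_ACTIVITIES = (
    "strength exercise leg extension",
    "strength exercise chest press",
    "strength exercise leg curl",
    "stretching yoga",
)


def _unit(v: tuple[float, float, float]) -> tuple[float, float, float]:
    n = math.sqrt(sum(c * c for c in v))
    return (v[0] / n, v[1] / n, v[2] / n)


@dataclass(frozen=True)
class ActivityProfile:
    """Generative description of one scripted activity.

    Parameters
    ----------
    name : str
        Activity name; the default catalog uses the study's 33 names.
    pa_type : {"sedentary", "locomotion", "lifestyle", "none"}
        Physical-activity type.
    met_mean, met_sd : float
        Mean and between-participant sd of the steady-state MET value.
    dom_freq_hz : float
        Frequency of the dominant wrist oscillation, Hz.
    amp_g : tuple of 3 floats
        Per-axis oscillation amplitude, g.
    gravity_axis : tuple of 3 floats
        Unit vector giving the static gravity component of each axis.
    noise_sd_g : float
        Standard deviation of i.i.d. Gaussian sensor noise per axis, g.
    """

    name: str
    pa_type: str
    met_mean: float
    met_sd: float
    dom_freq_hz: float
    amp_g: tuple[float, float, float]
    gravity_axis: tuple[float, float, float]
    noise_sd_g: float

    def __post_init__(self) -> None:
        if self.pa_type not in PA_TYPES:
            raise InputError(f"unknown pa_type {self.pa_type!r}")
        if not self.met_mean > 0:
            raise InputError("met_mean must be positive")
        if self.met_sd < 0:
            raise InputError("met_sd must be nonnegative")
        if self.dom_freq_hz < 0:
            raise InputError("dom_freq_hz must be nonnegative")
        if any(a < 0 for a in self.amp_g):
            raise InputError("amp_g must be nonnegative componentwise")
        if self.noise_sd_g < 0:
            raise InputError("noise_sd_g must be nonnegative")
        norm = float(np.linalg.norm(self.gravity_axis))
        if abs(norm - 1.0) > 1e-9:
            raise InputError("gravity_axis must be a unit vector")


def _p(name, pa_type, met_mean, met_sd, f, amp, grav, noise) -> ActivityProfile:
    return ActivityProfile(
        name=name,
        pa_type=pa_type,
        met_mean=met_mean,
        met_sd=met_sd,
        dom_freq_hz=f,
        amp_g=amp,
        gravity_axis=_unit(grav),
        noise_sd_g=noise,
    )


# name, type, MET mean, MET sd, dominant freq (Hz, multiples of 1/20 so every
# frequency is an exact bin of the 60-s window), per-axis amplitude (g),
# gravity direction (normalised below), noise sd (g)
_CATALOG_SPEC = [
    # sedentary — low intensity
    ("tv watching", "sedentary", 1.00, 0.05, 0.05, (0.002, 0.002, 0.002), (0.0, 0.0, 1.0), 0.005),
    ("computer work", "sedentary", 1.20, 0.05, 0.30, (0.020, 0.015, 0.005), (0.0, 0.6, 0.8), 0.005),
    ("standing still", "sedentary", 1.30, 0.05, 0.10, (0.005, 0.005, 0.005), (0.8, 0.0, 0.6), 0.005),
    # locomotion
    ("leisure walk", "locomotion", 2.60, 0.10, 1.70, (0.25, 0.15, 0.10), (0.7, 0.7, 0.0), 0.02),
    ("rapid walk", "locomotion", 3.80, 0.20, 2.10, (0.45, 0.25, 0.15), (0.7, 0.5, 0.5), 0.02),
    ("walking at rpe 1", "locomotion", 2.30, 0.10, 1.50, (0.20, 0.12, 0.08), (0.6, 0.8, 0.0), 0.02),
    ("walking at rpe 5", "locomotion", 4.30, 0.25, 2.30, (0.55, 0.30, 0.20), (0.5, 0.7, 0.5), 0.02),
    ("stair ascent", "locomotion", 4.00, 0.20, 1.90, (0.40, 0.30, 0.25), (0.6, 0.6, 0.53), 0.02),
    ("stair descent", "locomotion", 3.70, 0.15, 2.00, (0.35, 0.28, 0.22), (0.55, 0.65, 0.52), 0.02),
    # lifestyle
    ("light gardening", "lifestyle", 2.50, 0.10, 0.70, (0.15, 0.10, 0.08), (0.0, 0.8, 0.6), 0.015),
    ("yard work", "lifestyle", 4.00, 0.25, 0.95, (0.30, 0.20, 0.15), (0.3, 0.7, 0.65), 0.02),
    ("prepare serve meal", "lifestyle", 2.00, 0.10, 0.60, (0.10, 0.08, 0.05), (0.2, 0.9, 0.39), 0.01),
    ("digging", "lifestyle", 4.50, 0.30, 1.00, (0.35, 0.30, 0.20), (0.4, 0.6, 0.69), 0.02),
    ("straightening up dusting", "lifestyle", 2.35, 0.10, 0.75, (0.12, 0.10, 0.06), (0.1, 0.7, 0.71), 0.01),
    ("washing dishes", "lifestyle", 1.95, 0.10, 0.55, (0.08, 0.06, 0.04), (0.0, 0.9, 0.44), 0.01),
    ("unloading storing dishes", "lifestyle", 2.20, 0.10, 0.65, (0.12, 0.08, 0.06), (0.15, 0.85, 0.5), 0.01),
    ("personal care", "lifestyle", 1.95, 0.10, 0.50, (0.08, 0.07, 0.05), (0.3, 0.8, 0.52), 0.01),
    ("dressing", "lifestyle", 2.05, 0.10, 0.45, (0.10, 0.08, 0.06), (0.25, 0.75, 0.61), 0.01),
    ("sweeping", "lifestyle", 2.60, 0.10, 0.85, (0.18, 0.12, 0.08), (0.2, 0.6, 0.77), 0.015),
    ("vacuuming", "lifestyle", 2.50, 0.10, 0.80, (0.16, 0.12, 0.08), (0.25, 0.55, 0.8), 0.015),
    ("trash removal", "lifestyle", 2.45, 0.10, 0.90, (0.15, 0.10, 0.10), (0.35, 0.5, 0.79), 0.015),
    ("replacing sheets on a bed", "lifestyle", 2.55, 0.10, 0.70, (0.16, 0.14, 0.08), (0.3, 0.45, 0.84), 0.015),
    ("mopping", "lifestyle", 3.60, 0.15, 0.90, (0.20, 0.15, 0.10), (0.15, 0.5, 0.85), 0.015),
    ("light home maintenance", "lifestyle", 2.40, 0.10, 1.05, (0.14, 0.10, 0.08), (0.4, 0.4, 0.82), 0.015),
    ("heavy lifting", "lifestyle", 4.20, 0.25, 0.40, (0.30, 0.25, 0.20), (0.5, 0.3, 0.81), 0.02),
    ("shopping", "lifestyle", 2.30, 0.10, 1.10, (0.12, 0.10, 0.06), (0.45, 0.35, 0.82), 0.01),
    ("ironing", "lifestyle", 2.00, 0.10, 0.60, (0.09, 0.07, 0.05), (0.05, 0.95, 0.31), 0.01),
    ("laundry washing", "lifestyle", 2.10, 0.10, 0.50, (0.10, 0.09, 0.06), (0.1, 0.88, 0.46), 0.01),
    ("washing windows", "lifestyle", 2.50, 0.10, 0.95, (0.17, 0.13, 0.09), (0.0, 0.7, 0.71), 0.015),
    # excluded from type recognition
    ("strength exercise leg curl", "none", 3.60, 0.15, 0.35, (0.15, 0.12, 0.10), (0.9, 0.2, 0.39), 0.015),
    ("strength exercise chest press", "none", 3.80, 0.20, 0.40, (0.20, 0.15, 0.12), (0.85, 0.3, 0.43), 0.015),
    ("strength exercise leg extension", "none", 3.70, 0.15, 0.30, (0.14, 0.10, 0.08), (0.95, 0.1, 0.29), 0.015),
    ("stretching yoga", "none", 2.20, 0.10, 0.15, (0.06, 0.05, 0.04), (0.75, 0.4, 0.52), 0.01),
]


def default_catalog() -> list[ActivityProfile]:
    """Return the default 33-activity catalog (fresh list each call)."""
    return [_p(*row) for row in _CATALOG_SPEC]


def default_type_mapping() -> dict[str, str]:
    """Activity name -> physical-activity type for the default catalog."""
    return {p.name: p.pa_type for p in default_catalog()}
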