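"""Independent brute-force re-implementation of the 46 time-domain features.

Deliberately written along a different path from the package implementation:
scipy.stats for skewness/kurtosis, an explicit order-statistic interpolation
for quantiles, and plain arithmetic for the rest. Used only as a test oracle.
"""

import math

import numpy as np
from scipy import stats


def _quantile(v, q):
    s = np.sort(np.asarray(v, dtype=float))
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def _channel(v):
    v = np.asarray(v, dtype=float)
    n = len(v)
    mean = v.sum() / n
    dev = v - mean
    m2 = (dev**2).sum() / n
    m3 = (dev**3).sum() / n
    m4 = (dev**4).sum() / n
    sd = math.sqrt((dev**2).sum() / (n - 1)) if n > 1 else 0.0
    if m2 < 1e-24:
        skew, kurt = 0.0, 0.0
    else:
        skew = float(stats.skew(v, bias=True))
        kurt = float(stats.kurtosis(v, bias=True, fisher=False))
    return {
        "mean": mean,
        "sd": sd,
        "min": v.min(),
        "max": v.max(),
        "q25": _quantile(v, 0.25),
        "q75": _quantile(v, 0.75),
        "m3": m3,
        "m4": m4,
        "skew": skew,
        "kurt": kurt,
    }


def _cv(sd, mean):
    return 0.0 if abs(mean) < 1e-6 else 100.0 * sd / abs(mean)


def brute_force_time_features(data):
    """All 46 time-domain features of an (n, 3) window, by brute force."""
    data = np.asarray(data, dtype=float)
    x, y, z = data[:, 0], data[:, 1], data[:, 2]
    vm = np.array([math.sqrt(a * a + b * b + c * c) for a, b, c in zip(x, y, z)])
    angles = np.array(
        [
            math.degrees(math.asin(max(-1.0, min(1.0, a / v)))) if v > 0 else 0.0
            for a, v in zip(x, vm)
        ]
    )
    ch = {"vm": _channel(vm), "x": _channel(x), "y": _channel(y), "z": _channel(z)}
    out = {
        "mvm": ch["vm"]["mean"],
        "sdvm": ch["vm"]["sd"],
        "mangle": angles.sum() / len(angles),
        "sdangle": _channel(angles)["sd"],
    }
    for a in "xyz":
        out[f"mean_{a}"] = ch[a]["mean"]
    for a in "xyz":
        out[f"sd_{a}"] = ch[a]["sd"]
    for a in "xyz":
        out[f"cv_{a}"] = _cv(ch[a]["sd"], ch[a]["mean"])
    for c in ("vm", "x", "y", "z"):
        out[f"min_{c}"] = ch[c]["min"]
    for c in ("vm", "x", "y", "z"):
        out[f"max_{c}"] = ch[c]["max"]
    for c in ("vm", "x", "y", "z"):
        out[f"lower_{c}_25"] = ch[c]["q25"]
    for c in ("vm", "x", "y", "z"):
        out[f"upper_{c}_75"] = ch[c]["q75"]
    for c in ("vm", "x", "y", "z"):
        out[f"third_moment_{c}"] = ch[c]["m3"]
    for c in ("vm", "x", "y", "z"):
        out[f"fourth_moment_{c}"] = ch[c]["m4"]
    for c in ("vm", "x", "y", "z"):
        out[f"skewness_{c}"] = ch[c]["skew"]
    for c in ("vm", "x", "y", "z"):
        out[f"kurtosis_{c}"] = ch[c]["kurt"]
    out["cv_vm"] = _cv(ch["vm"]["sd"], ch["vm"]["mean"])
    return out


def random_structured_window(rng, n):
    """A gravity + sinusoid + noise window, parameters drawn at random."""
    g = rng.normal(size=3)
    g /= np.linalg.norm(g)
    amp = rng.uniform(0.0, 0.6, size=3)
    f = rng.uniform(0.1, 5.0)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    t = np.arange(n)
    noise_sd = rng.uniform(0.0, 0.05)
    data = (
        g[None, :]
        + amp[None, :] * np.sin(2 * np.pi * f * t[:, None] / n + phase[None, :])
        + rng.normal(0, noise_sd, size=(n, 3))
    )
    return data
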