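"""Windowing and the 49 features: examples, invariants, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import brute_force_time_features, random_structured_window
from wristpa.exceptions import InputError
from wristpa.features import (
    FEATURE_NAMES,
    TIME_FEATURE_NAMES,
    WindowSlice,
    angle_to_vertical,
    extract_features,
    extract_freq_features,
    extract_time_features,
    segment_windows,
    vector_magnitude,
)
from wristpa.ingest import RawRecording


def _recording(duration_s, rate=30):
    n = round(duration_s * rate)
    return RawRecording(
        "P1", "V1", rate, t=np.arange(n) / rate, x=np.zeros(n), y=np.zeros(n), z=np.ones(n)
    )


def _intervals(end_s, start_s=0.0):
    return pd.DataFrame(
        [{"participant_id": "P1", "visit_id": "V1", "activity_name": "tv watching",
          "start_s": start_s, "end_s": end_s, "met": 1.0}]
    )


@pytest.mark.parametrize("duration,expected", [(600, 10), (59, 0), (130, 2)])
def test_window_counts_floor_the_interval_length(duration, expected):
    rec = _recording(duration)
    slices = segment_windows(rec, _intervals(duration))
    assert len(slices) == expected
    for s in slices:
        assert s.data.shape == (round(60 * rec.rate_hz), 3)


def test_interval_outside_recording_is_rejected():
    rec = _recording(100)
    with pytest.raises(InputError):
        segment_windows(rec, _intervals(150.0))


@pytest.mark.parametrize(
    "xyz,expected",
    [((0.0, 0.0, 1.0), 1.0), ((1.0, 2.0, 2.0), 3.0), ((0.0, 0.0, 0.0), 0.0)],
)
def test_vector_magnitude_examples(xyz, expected):
    x, y, z = ([v] for v in xyz)
    assert vector_magnitude(x, y, z)[0] == pytest.approx(expected)


def test_angle_examples():
    assert angle_to_vertical([0.0], [1.0])[0] == pytest.approx(0.0)
    assert angle_to_vertical([1.0], [1.0])[0] == pytest.approx(90.0)
    assert angle_to_vertical([1.0], [2.0])[0] == pytest.approx(30.0)  # asin(1/2)
    assert angle_to_vertical([0.0], [0.0])[0] == 0.0  # zero-VM guard


def test_constant_window_statistics():
    data = np.tile([0.0, 0.0, 1.0], (120, 1))
    f = extract_time_features(data)
    assert f["mvm"] == 1.0 and f["sdvm"] == 0.0
    assert f["mangle"] == 0.0 and f["sdangle"] == 0.0
    assert f["cv_vm"] == 0.0
    assert f["min_vm"] == f["max_vm"] == 1.0
    for c in ("vm", "x", "y", "z"):
        assert f[f"third_moment_{c}"] == 0.0
        assert f[f"fourth_moment_{c}"] == 0.0
        assert f[f"skewness_{c}"] == 0.0  # constant-signal guard
        assert f[f"kurtosis_{c}"] == 0.0


def test_four_sample_moment_example():
    # z = {1, 1, 1, 5}: mean 2, sample sd 2 (m2 = 3 population),
    # m3 = mean({-1,-1,-1,3}^3) = 24/4 = 6, skewness = 6 / 3^1.5
    data = np.column_stack([np.zeros(4), np.zeros(4), np.array([1.0, 1.0, 1.0, 5.0])])
    f = extract_time_features(data)
    assert f["mean_z"] == pytest.approx(2.0)
    assert f["sd_z"] == pytest.approx(2.0)
    assert f["third_moment_z"] == pytest.approx(6.0)
    assert f["skewness_z"] == pytest.approx(6.0 / 3.0**1.5)
    # VM of this window equals |z|, so the VM block matches
    assert f["third_moment_vm"] == pytest.approx(6.0)
    # independent brute-force re-check of the same slice
    oracle = brute_force_time_features(data)
    for k in ("mean_z", "sd_z", "third_moment_z", "skewness_z", "kurtosis_z"):
        assert f[k] == pytest.approx(oracle[k], rel=1e-12)


def test_order_statistics_are_ordered(rng):
    data = rng.normal(size=(600, 3))
    f = extract_time_features(data)
    for c in ("vm", "x", "y", "z"):
        assert f[f"min_{c}"] <= f[f"lower_{c}_25"] <= f[f"upper_{c}_75"] <= f[f"max_{c}"]


@pytest.mark.parametrize("rate", [30, 80, 100])
def test_feature_vector_has_49_keys_in_canonical_order(rate, rng):
    data = random_structured_window(rng, round(60 * rate))
    f = extract_features(data, rate)
    assert list(f) == FEATURE_NAMES
    assert len(f) == 49
    assert all(np.isfinite(v) for v in f.values())
    # repeated call is identical
    assert extract_features(data, rate) == f


def test_incomplete_window_is_rejected(rng):
    with pytest.raises(InputError):
        extract_features(rng.normal(size=(100, 3)), 30)
    with pytest.raises(InputError):
        extract_freq_features(rng.normal(size=(100,)), 30)


def test_freq_features_recover_inband_tone():
    t = np.arange(6000) / 100.0
    vm = 1.0 + 0.5 * np.sin(2 * np.pi * 1.5 * t)
    f = extract_freq_features(vm, 100)
    assert f["df"] == pytest.approx(1.5)  # 90/60 Hz, an exact bin
    assert f["p625"] >= 0.99
    assert f["fpdf"] >= 0.99


def test_freq_features_reject_out_of_band_tone():
    t = np.arange(6000) / 100.0
    vm = 1.0 + 0.5 * np.sin(2 * np.pi * 5.0 * t)
    f = extract_freq_features(vm, 100)
    assert f["df"] == pytest.approx(5.0)
    assert f["p625"] <= 0.01


def test_constant_vm_yields_zero_spectrum_guard():
    f = extract_freq_features(np.ones(1800), 30)
    assert f == {"p625": 0.0, "df": 0.0, "fpdf": 0.0}


@given(seed=st.integers(0, 10_000))
def test_spectral_features_are_bounded(seed):
    rng = np.random.default_rng(seed)
    data = random_structured_window(rng, 1800)
    f = extract_features(data, 30)
    assert 0.0 <= f["p625"] <= 1.0
    assert 0.0 <= f["fpdf"] <= 1.0
    assert f["df"] == 0.0 or 0.0 < f["df"] <= 15.0


@given(c=st.floats(0.1, 10.0), seed=st.integers(0, 1000))
def test_scale_equivariance(c, seed):
    rng = np.random.default_rng(seed)
    data = random_structured_window(rng, 300)
    f1 = extract_time_features(data)
    f2 = extract_time_features(c * data)
    for name in ("mvm", "sdvm", "min_vm", "max_vm", "lower_vm_25", "upper_vm_75"):
        assert f2[name] == pytest.approx(c * f1[name], rel=1e-9, abs=1e-12)
    assert f2["third_moment_vm"] == pytest.approx(c**3 * f1["third_moment_vm"], rel=1e-9, abs=1e-12)
    assert f2["fourth_moment_vm"] == pytest.approx(c**4 * f1["fourth_moment_vm"], rel=1e-9, abs=1e-12)
    for name in ("cv_vm", "skewness_vm", "kurtosis_vm", "mangle", "sdangle", "cv_x"):
        assert f2[name] == pytest.approx(f1[name], rel=1e-7, abs=1e-9)


def test_time_features_match_brute_force_oracle(rng):
    for _ in range(100):
        data = random_structured_window(rng, 900)
        mine = extract_time_features(data)
        oracle = brute_force_time_features(data)
        for name in TIME_FEATURE_NAMES:
            assert np.isclose(mine[name], oracle[name], rtol=1e-9, atol=1e-12), name


def test_windows_anchor_at_interval_start():
    rate = 30
    n = round(130 * rate)
    t = np.arange(n) / rate
    z = np.where(t < 10.0, 5.0, 1.0)  # marker before the interval starts
    rec = RawRecording("P1", "V1", rate, t=t, x=np.zeros(n), y=np.zeros(n), z=z)
    slices = segment_windows(rec, _intervals(end_s=130.0, start_s=10.0))
    assert len(slices) == 2
    assert np.allclose(slices[0].data[:, 2], 1.0)  # marker excluded
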