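"""Spectral preprocessing: band bank construction, Hilbert envelopes,
epoching, baseline z-scoring, artifact rejection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statewave import preprocessing as pp


def make_recording(data, fs=500.0, events=()):
    labels = [f"c{i}" for i in range(np.atleast_2d(data).shape[0])]
    return pp.Recording(np.atleast_2d(data), fs, labels, events=list(events))


# ---------------------------------------------------------------------------
# Band bank


def test_band_bank_default_endpoints_and_count():
    bb = pp.build_band_bank()
    assert len(bb) == 27
    assert bb.centers[0] == pytest.approx(3.0)
    assert bb.centers[-1] == pytest.approx(180.0)


def test_band_bank_geometric_progression_midpoint():
    bb = pp.build_band_bank()
    # 14th center of the geometric progression from 3 to 180: 3 * sqrt(60)
    assert bb.centers[13] == pytest.approx(3 * np.sqrt(60))


def test_band_edges_from_relative_bandwidth():
    bb = pp.build_band_bank(100, 200, n_bands=2, rel_bw=0.3)
    c, lo, hi = bb.bands[0]
    assert (lo, hi) == (pytest.approx(85.0), pytest.approx(115.0))


def test_band_bank_nyquist_guard():
    with pytest.raises(ValueError, match="Nyquist"):
        pp.build_band_bank(sampling_rate=300.0)  # top edge 207 Hz >= 150


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    f_min=st.floats(0.5, 10),
    ratio=st.floats(2, 100),
    n=st.integers(2, 40),
    bw=st.floats(0.05, 0.8),
)
def test_band_bank_strictly_increasing_nondegenerate(f_min, ratio, n, bw):
    bb = pp.build_band_bank(f_min, f_min * ratio, n, bw)
    centers = bb.centers
    assert np.all(np.diff(centers) > 0)
    for c, lo, hi in bb.bands:
        assert 0 < lo < c < hi
        assert hi - lo == pytest.approx(bw * c)


# ---------------------------------------------------------------------------
# Envelope extraction


def test_envelope_of_in_band_sinusoid_recovers_amplitude():
    fs = 500.0
    t = np.arange(0, 10, 1 / fs)
    rec = make_recording(2.0 * np.sin(2 * np.pi * 100 * t), fs)
    env = pp.bandpass_hilbert_envelope(rec, (85, 115))
    interior = env.data[0, int(fs) : -int(fs)]
    assert np.abs(interior - 2.0).max() / 2.0 < 0.02
    assert (env.data >= 0).all()


def test_envelope_out_of_band_attenuation_40db():
    fs = 500.0
    t = np.arange(0, 10, 1 / fs)
    rec = make_recording(np.sin(2 * np.pi * 20 * t), fs)
    env = pp.bandpass_hilbert_envelope(rec, (85, 115))
    peak = env.data[0, int(fs) : -int(fs)].max()
    assert 20 * np.log10(peak) < -40


def test_envelope_recovers_am_modulation():
    fs, fm, fc, c, m = 500.0, 2.0, 100.0, 1.5, 0.5
    t = np.arange(0, 10, 1 / fs)
    sig = c * (1 + m * np.cos(2 * np.pi * fm * t)) * np.cos(2 * np.pi * fc * t)
    env = pp.bandpass_hilbert_envelope(make_recording(sig, fs), (80, 125))
    target = c * (1 + m * np.cos(2 * np.pi * fm * t))
    sl = slice(int(fs), -int(fs))
    assert np.abs(env.data[0, sl] - target[sl]).max() / target[sl].min() < 0.05


def test_zero_phase_filter_symmetric_impulse_response():
    fs = 500.0
    x = np.zeros(2001)
    x[1000] = 1.0
    out = pp.bandpass(make_recording(x, fs), (8, 12)).data[0]
    assert out[900:1000] == pytest.approx(out[1100:1000:-1], abs=1e-7)


def test_band_outside_nyquist_rejected():
    rec = make_recording(np.zeros(1000), 500.0)
    with pytest.raises(ValueError):
        pp.bandpass_hilbert_envelope(rec, (200, 300))


# ---------------------------------------------------------------------------
# Epoching


def _rec_with_events(n_events=3, fs=500.0, dur=10.0, kind="stim"):
    rng = np.random.default_rng(7)
    data = rng.normal(0, 1, (2, int(dur * fs)))
    events = [pp.Event(time=1.0 + i * 2.0, kind=kind) for i in range(n_events)]
    return pp.Recording(data, fs, ["a", "b"], events=events)


def test_extract_epochs_sample_count_convention():
    rec = _rec_with_events()
    ep = pp.extract_epochs(rec, "stim", (-0.3, 0.7))
    assert ep.n_samples == 500  # 1 s at 500 Hz, half-open window
    assert ep.n_trials == 3
    assert ep.times[0] == pytest.approx(-0.3)
    assert ep.times[-1] < 0.7  # t = 0.7 excluded


def test_extract_epochs_no_matching_events_is_empty_with_shape():
    rec = _rec_with_events()
    ep = pp.extract_epochs(rec, "nothing", (-0.3, 0.7))
    assert ep.n_trials == 0
    assert ep.data.shape == (0, 2, 500)


def test_extract_epochs_constant_recording_identical_epochs():
    rec = pp.Recording(
        np.full((1, 5000), 3.14),
        500.0,
        ["a"],
        events=[pp.Event(1.0, "stim"), pp.Event(3.0, "stim")],
    )
    ep = pp.extract_epochs(rec, "stim", (-0.3, 0.7))
    assert np.all(ep.data == 3.14)
    assert np.array_equal(ep.data[0], ep.data[1])


def test_extract_epochs_drops_out_of_bounds_events():
    rec = pp.Recording(
        np.zeros((1, 1000)),
        500.0,
        ["a"],
        events=[pp.Event(0.1, "stim"), pp.Event(1.0, "stim"), pp.Event(1.9, "stim")],
    )
    ep = pp.extract_epochs(rec, "stim", (-0.3, 0.7))
    assert ep.n_trials == 1  # first starts before 0, last ends after 2 s


# ---------------------------------------------------------------------------
# Baseline z-scoring


def _epochs_from_array(data, fs=500.0, window=(-0.3, 0.7)):
    n = data.shape[0]
    return pp.Epochs(
        data=data,
        window=window,
        sampling_rate=fs,
        channel_labels=[f"c{i}" for i in range(data.shape[1])],
        metadata=pd.DataFrame({"event_time": np.arange(n, dtype=float)}),
    )


def test_baseline_zscore_identity_when_baseline_standard(rng):
    data = rng.normal(0, 1, (2, 1, 500))
    # force each trial's baseline (samples 50..149, i.e. -0.2..0 s) to mean 0, sd 1
    bl = slice(50, 150)
    for tr in range(2):
        seg = data[tr, 0, bl]
        data[tr, 0, bl] = (seg - seg.mean()) / seg.std(ddof=1)
    z = pp.baseline_zscore(_epochs_from_array(data), (-0.2, 0.0))
    assert z.data == pytest.approx(data, abs=1e-10)
    assert z.baseline_state == "z_scored"


def test_baseline_zscore_hand_example():
    data = np.zeros((1, 1, 500))
    bl = slice(50, 150)
    rng = np.random.default_rng(3)
    seg = rng.normal(0, 1, 100)
    seg = (seg - seg.mean()) / seg.std(ddof=1)  # mean 0, sd 1
    data[0, 0, bl] = 2.0 + 0.5 * seg  # baseline mean 2, sample sd 0.5
    data[0, 0, 300] = 4.0
    z = pp.baseline_zscore(_epochs_from_array(data), (-0.2, 0.0))
    assert z.data[0, 0, 300] == pytest.approx((4.0 - 2.0) / 0.5)


def test_baseline_zscore_constant_epoch_rejected():
    data = np.ones((1, 1, 500))
    with pytest.raises(ValueError, match="zero baseline variance"):
        pp.baseline_zscore(_epochs_from_array(data), (-0.2, 0.0))


def test_baseline_outside_window_rejected(rng):
    data = rng.normal(0, 1, (2, 1, 500))
    with pytest.raises(ValueError):
        pp.baseline_zscore(_epochs_from_array(data), (-0.5, 0.0))


def test_envelope_zscore_commutes_with_trial_reordering(rng):
    data = rng.normal(0, 1, (6, 2, 500)) ** 2  # envelope-like, positive
    z = pp.baseline_zscore(_epochs_from_array(data), (-0.2, 0.0))
    perm = np.array([3, 1, 5, 0, 4, 2])
    z_perm = pp.baseline_zscore(_epochs_from_array(data[perm]), (-0.2, 0.0))
    assert z_perm.data == pytest.approx(z.data[perm])


# ---------------------------------------------------------------------------
# Artifact rejection


def test_reject_artifacts_identical_trials_keep_all(rng):
    one = rng.normal(0, 1, (1, 2, 500))
    data = np.repeat(one, 5, axis=0)
    kept, rejected = pp.reject_artifacts(_epochs_from_array(data))
    assert rejected.sum() == 0
    assert kept.n_trials == 5


def test_reject_artifacts_single_outlier(rng):
    data = rng.normal(0, 1, (100, 1, 500))
    data[17] *= np.sqrt(1000.0)
    kept, rejected = pp.reject_artifacts(_epochs_from_array(data), variance_factor=4)
    assert rejected.sum() == 1
    assert rejected[17]
    assert kept.n_trials == 99


def test_reject_artifacts_infinite_factor_keeps_all(rng):
    data = rng.normal(0, 1, (10, 1, 500))
    data[3] *= 100
    _, rejected = pp.reject_artifacts(_epochs_from_array(data), variance_factor=np.inf)
    assert rejected.sum() == 0


def test_reject_artifacts_needs_two_trials(rng):
    with pytest.raises(ValueError):
        pp.reject_artifacts(_epochs_from_array(rng.normal(0, 1, (1, 1, 500))))
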