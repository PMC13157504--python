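"""Spectral preprocessing: band decomposition, Hilbert envelopes, epoching,
baseline z-scoring and variance-based artifact rejection.

Filters are fourth-order Butterworth IIR applied forward–backward
(zero-phase), so filtered features carry no group delay — important for the
onset-latency analyses downstream.  Sample standard deviations use the n−1
denominator throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "Event",
    "Recording",
    "BandBank",
    "Epochs",
    "build_band_bank",
    "bandpass",
    "bandpass_hilbert_envelope",
    "extract_epochs",
    "baseline_zscore",
    "reject_artifacts",
]


@dataclass
class Event:
    time: float  # seconds from recording start
    kind: str
    payload: dict = field(default_factory=dict)


@dataclass
class Recording:
    """Multichannel time series with a sampling rate and an event list."""

    data: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float
    channel_labels: list[str]
    events: list[Event] = field(default_factory=list)
    channel_groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        dur = self.duration
        for ev in self.events:
            if not (0.0 <= ev.time <= dur):
                raise ValueError(f"event at {ev.time} s outside recording [0, {dur}]")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def events_of_kind(self, kind: str) -> list[Event]:
        return [ev for ev in self.events if ev.kind == kind]


@dataclass
class BandBank:
    """Ordered list of (center, low, high) frequency bands in Hz."""

    bands: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        centers = [b[0] for b in self.bands]
        if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
            raise ValueError("band centers must be strictly increasing")
        for c, lo, hi in self.bands:
            if not (0 < lo < c < hi):
                raise ValueError(f"degenerate band ({c}, {lo}, {hi})")

    @property
    def centers(self) -> np.ndarray:
        return np.array([b[0] for b in self.bands])

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)


def build_band_bank(
    f_min: float = 3.0,
    f_max: float = 180.0,
    n_bands: int = 27,
    rel_bw: float = 0.3,
    sampling_rate: float | None = None,
) -> BandBank:
    """Geometric progression of band centers with relative-bandwidth edges.

    Centers follow ``f_k = f_min * (f_max/f_min)**((k-1)/(n_bands-1))`` and
    each band spans ``center * (1 ± rel_bw/2)`` — a total width equal to
    ``rel_bw`` times the center frequency.  If ``sampling_rate`` is given,
    any band edge at or above Nyquist raises a configuration error.
    """
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    if not (0 < rel_bw < 2):
        raise ValueError("rel_bw must lie in (0, 2)")
    k = np.arange(n_bands)
    centers = f_min * (f_max / f_min) ** (k / (n_bands - 1))
    bands = [(float(c), float(c * (1 - rel_bw / 2)), float(c * (1 + rel_bw / 2))) for c in centers]
    if sampling_rate is not None:
        nyq = sampling_rate / 2.0
        bad = [b for b in bands if b[2] >= nyq]
        if bad:
            raise ValueError(
                f"{len(bad)} band(s) reach the Nyquist frequency {nyq} Hz "
                f"(highest edge {bad[-1][2]:.1f} Hz)"
            )
    return BandBank(bands)


def _butter_sos(band: tuple[float, float], fs: float, order: int = 4):
    lo, hi = band
    nyq = fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} must lie strictly inside (0, {nyq}) Hz")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass(recording: Recording, band: tuple[float, float], order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of every channel."""
    sos = _butter_sos(band, recording.sampling_rate, order)
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    return replace(recording, data=filtered)


def bandpass_hilbert_envelope(
    recording: Recording, band: tuple[float, float], order: int = 4
) -> Recording:
    """Band-pass filter then per-channel Hilbert analytic amplitude.

    The result is the instantaneous amplitude (envelope) of the band-limited
    signal: non-negative, zero group delay.
    """
    filtered = bandpass(recording, band, order)
    env = np.abs(signal.hilbert(filtered.data, axis=1))
    return replace(recording, data=env)


@dataclass
class Epochs:
    """Trials × channels × samples around an event, plus trial metadata.

    The epoch window is half-open ``[start, end)`` relative to the event;
    the sample at t = 0 belongs to the post-stimulus interval.
    """

    data: np.ndarray  # (n_trials, n_channels, n_samples)
    window: tuple[float, float]
    sampling_rate: float
    channel_labels: list[str]
    metadata: pd.DataFrame  # one row per trial
    baseline_state: str = "raw"  # raw | baseline_corrected | z_scored
    band: tuple[float, float, float] | None = None  # (center, low, high) if envelope

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (trials, channels, samples)")
        n_expected = int(round((self.window[1] - self.window[0]) * self.sampling_rate))
        if abs(self.data.shape[2] - n_expected) > 1:
            raise ValueError(
                f"window/sample-count mismatch: {self.data.shape[2]} vs {n_expected}"
            )
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata rows must match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_samples) / self.sampling_rate

    def time_mask(self, start: float, end: float) -> np.ndarray:
        """Boolean mask for the half-open interval [start, end)."""
        t = self.times
        return (t >= start - 1e-12) & (t < end - 1e-12)

    def select(self, idx: np.ndarray) -> "Epochs":
        return replace(self, data=self.data[idx], metadata=self.metadata.iloc[idx].reset_index(drop=True))


def extract_epochs(
    recording: Recording,
    event_kind: str,
    window: tuple[float, float] = (-0.3, 0.7),
) -> Epochs:
    """One epoch per matching event, half-open window relative to the event.

    Events whose windows extend past the recording boundary are dropped with
    a log entry; their rows do not appear in the metadata.
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed start")
    fs = recording.sampling_rate
    n_samp = int(round((end - start) * fs))
    rows, meta_rows, dropped = [], [], 0
    for ev in recording.events_of_kind(event_kind):
        i0 = int(round((ev.time + start) * fs))
        if i0 < 0 or i0 + n_samp > recording.n_samples:
            dropped += 1
            continue
        rows.append(recording.data[:, i0 : i0 + n_samp])
        meta_rows.append({"event_time": ev.time, **ev.payload})
    if dropped:
        logger.info("extract_epochs: dropped %d event(s) outside the recording", dropped)
    data = np.stack(rows) if rows else np.empty((0, recording.n_channels, n_samp))
    meta = pd.DataFrame(meta_rows) if meta_rows else pd.DataFrame({"event_time": []})
    return Epochs(
        data=data,
        window=window,
        sampling_rate=fs,
        channel_labels=list(recording.channel_labels),
        metadata=meta,
    )


def baseline_zscore(
    epochs: Epochs, baseline: tuple[float, float] = (-0.2, 0.0)
) -> Epochs:
    """Per-trial, per-channel z-scoring against that trial's baseline.

    For each trial and channel the baseline mean is subtracted and the
    result divided by the baseline sample standard deviation (n−1) at every
    time point.  Trials with zero baseline variance in any channel are
    excluded and logged; if nothing survives, an error is raised.
    """
    if not (epochs.window[0] <= baseline[0] < baseline[1] <= epochs.window[1]):
        raise ValueError("baseline interval must lie within the epoch window")
    mask = epochs.time_mask(*baseline)
    if mask.sum() < 2:
        raise ValueError("baseline interval contains fewer than 2 samples")
    base = epochs.data[:, :, mask]
    mu = base.mean(axis=2, keepdims=True)
    sd = base.std(axis=2, ddof=1, keepdims=True)
    ok = np.all(sd[:, :, 0] > 0, axis=1)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("baseline_zscore: excluded %d trial(s) with zero baseline variance", n_bad)
    if not ok.any():
        raise ValueError("all trials have zero baseline variance")
    z = (epochs.data[ok] - mu[ok]) / sd[ok]
    return replace(
        epochs,
        data=z,
        metadata=epochs.metadata.loc[ok].reset_index(drop=True),
        baseline_state="z_scored",
    )


def baseline_correct(epochs: Epochs, baseline: tuple[float, float]) -> Epochs:
    """Subtract the per-trial, per-channel baseline mean (no scaling)."""
    if not (epochs.window[0] <= baseline[0] < baseline[1] <= epochs.window[1]):
        raise ValueError("baseline interval must lie within the epoch window")
    mask = epochs.time_mask(*baseline)
    mu = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - mu, baseline_state="baseline_corrected")


def reject_artifacts(
    epochs: Epochs, variance_factor: float = 4.0
) -> tuple[Epochs, np.ndarray]:
    """Exclude trials whose channel-averaged variance exceeds
    ``variance_factor`` times the mean variance across trials.

    Returns the surviving epochs and a boolean mask (True = rejected).
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials")
    trial_var = epochs.data.var(axis=2, ddof=1).mean(axis=1)  # (n_trials,)
    threshold = variance_factor * trial_var.mean()
    rejected = trial_var > threshold
    if rejected.any():
        logger.info(
            "reject_artifacts: rejected %d/%d trial(s) (%.2f%%)",
            int(rejected.sum()),
            epochs.n_trials,
            100.0 * rejected.mean(),
        )
    kept = epochs.select(np.flatnonzero(~rejected))
    return kept, rejected
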