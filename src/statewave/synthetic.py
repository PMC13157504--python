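"""Synthetic session generator.

Emulates the statistical structure of an experience-sampling visual
discrimination experiment recorded with a multichannel neural sensor array:

* a latent 5-level attentional rating that resets toward ON (task-focused)
  after each thought probe and then drifts toward OFF (mind-wandering) with
  a per-trial hazard;
* state-dependent theta-band (5–9 Hz) oscillatory power, stronger in OFF;
* a stimulus-evoked broadband high-frequency burst (band-limited noise under
  a smooth amplitude window) whose size scales with target tilt and state;
* an early C1-like evoked deflection whose polarity flips between upper and
  lower visual-field stimulation;
* behavior: logistic accuracy over tilt angle with state-specific
  parameters, and shifted-lognormal reaction times that are slower and more
  variable in the OFF state.

All randomness flows through one explicit seed; per-purpose substreams are
derived deterministically, so a session is bitwise reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .preprocessing import Event, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "LatentStateTrajectory",
    "SyntheticSession",
    "PARADIGM_ANGLES",
    "rating_to_state",
    "make_probe_schedule",
    "make_state_trajectory",
    "simulate_behavior",
    "generate_session",
    "generate_cohort",
]

#: Unsigned tilt angles of the paradigm: ten steps of 1.5 deg, 1.5..15.
PARADIGM_ANGLES = tuple(round(1.5 * k, 1) for k in range(1, 11))

STATES = ("OFF", "MID", "ON")


def rating_to_state(rating: int) -> str:
    """Group the 5-point rating: OFF = {1, 2}, MID = {3}, ON = {4, 5}."""
    if rating in (1, 2):
        return "OFF"
    if rating == 3:
        return "MID"
    if rating in (4, 5):
        return "ON"
    raise ValueError(f"rating must be 1..5, got {rating}")


# Per-state logistic accuracy parameters (a, b, c, d) for
# f(x) = a + (b - a) / (1 + exp(-(c x + d))).  Calibrated (least squares)
# so that the mean sub-threshold (1.5-4.5 deg) and supra-threshold
# (7.5-15 deg) accuracies and the 75%-correct threshold reproduce the
# study-condition pattern: OFF near/below chance for sub-threshold tilts
# (~49%) but only mildly worse supra-threshold (~78% vs ~84% in ON), with
# comparable thresholds (5.8-6.6 deg) across states.
DEFAULT_PSYCHOMETRIC = {
    "OFF": (0.294, 0.778, 1.23, -4.30),
    "MID": (0.647, 0.802, 1.56, -9.56),
    "ON": (0.646, 0.837, 1.83, -10.47),
}

# Per-state reaction-time (mean_s, sd_s) of the shifted-lognormal RT model.
DEFAULT_RT = {
    "OFF": (0.62, 0.25),
    "MID": (0.55, 0.17),
    "ON": (0.50, 0.15),
}


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic session.

    Durations in seconds, rates in Hz, angles in degrees.  The defaults are
    the conditions the analyses assume: ~1.91 s trials, thought probes on
    20% of trials (never adjacent), 500 Hz sampling, 5–9 Hz theta carrier
    with OFF/ON power ratio ``theta_state_gain``, an evoked high-frequency
    burst inside ``bha_window`` and a C1-like deflection peaking at
    ``c1_peak`` whose polarity flips with the visual field.
    """

    n_trials: int = 500
    trial_duration: float = 1.91
    pre_stim: float = 0.5  # stimulus onset within each trial
    probe_fraction: float = 0.2
    n_channels: int = 6
    n_occipital: int | None = None  # default: half the channels
    sampling_rate: float = 500.0

    # latent state process; the default hazard makes the stationary rating
    # distribution approximate the study conditions (~21% OFF, ~47% ON)
    drift_rate: float = 0.45  # per-trial hazard of moving one level toward OFF
    start_rating: int = 5

    # oscillatory / evoked components
    theta_freq: float = 6.0
    theta_amp: float = 1.0
    theta_state_gain: float = 2.0  # OFF / ON theta power ratio
    bha_amp: float = 3.0
    bha_band: tuple[float, float] = (80.0, 125.0)  # synthesized carrier band
    bha_window: tuple[float, float] = (0.05, 0.288)  # burst support, post-stimulus
    bha_peak_time: float = 0.144
    bha_gain_by_state: dict = field(
        default_factory=lambda: {"OFF": 0.7, "MID": 0.85, "ON": 1.0}
    )
    bha_state_gain_window: tuple[float, float] | None = None  # restrict state gain
    c1_amp: float = 1.5
    c1_onset: float = 0.049
    c1_peak: float = 0.068
    noise_sd: float = 1.0

    # behavior
    psychometric_params: dict = field(default_factory=lambda: dict(DEFAULT_PSYCHOMETRIC))
    rt_params: dict = field(default_factory=lambda: dict(DEFAULT_RT))
    rt_shift: float = 0.25  # shift of the lognormal RT body
    # per-session (between-subject) jitter
    rt_mean_jitter_sd: float = 0.04
    psych_shift_jitter_sd: float = 0.4
    # one multiplicative responsiveness factor per subject, applied to both
    # evoked components (C1 and the high-frequency burst): subjects with
    # stronger evoked responses are stronger in both, which is what couples
    # C1 and burst amplitude across subjects
    response_gain_jitter_sd: float = 0.25

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0.0 < self.probe_fraction <= 0.5):
            raise ValueError("probe_fraction must lie in (0, 0.5]")
        for name in ("trial_duration", "pre_stim", "sampling_rate", "theta_freq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pre_stim >= self.trial_duration:
            raise ValueError("pre_stim must be shorter than the trial")
        if not 1 <= self.start_rating <= 5:
            raise ValueError("start_rating must be 1..5")
        if not (0.0 <= self.drift_rate <= 1.0):
            raise ValueError("drift_rate must lie in [0, 1]")
        f_highest = max(self.bha_band[1], self.theta_freq)
        if self.sampling_rate < 4.0 * f_highest:
            raise ValueError(
                f"sampling_rate must be >= 4x the highest synthesized frequency "
                f"({f_highest} Hz)"
            )
        if not (0 < self.bha_band[0] < self.bha_band[1]):
            raise ValueError("invalid bha_band")
        if not (self.bha_window[0] < self.bha_peak_time < self.bha_window[1]):
            raise ValueError("bha_peak_time must lie inside bha_window")
        if not (0 <= self.c1_onset < self.c1_peak):
            raise ValueError("need 0 <= c1_onset < c1_peak")
        missing = [s for s in STATES if s not in self.bha_gain_by_state]
        if missing:
            raise ValueError(f"bha_gain_by_state missing states {missing}")

    @property
    def occipital_channels(self) -> int:
        return self.n_occipital if self.n_occipital is not None else max(1, self.n_channels // 2)


@dataclass
class LatentStateTrajectory:
    """Ground-truth per-trial rating (1–5) and derived 3-class label."""

    ratings: np.ndarray  # (n_trials,) int, 1..5

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=int)
        if self.ratings.ndim != 1 or np.any((self.ratings < 1) | (self.ratings > 5)):
            raise ValueError("ratings must be a 1-D array of levels 1..5")

    @property
    def labels(self) -> np.ndarray:
        return np.array([rating_to_state(r) for r in self.ratings])


@dataclass
class SyntheticSession:
    """A generated session: recording + trial table + retained ground truth."""

    recording: Recording
    trials: pd.DataFrame
    truth: LatentStateTrajectory
    config: SimulationConfig
    components: dict | None = None  # per-component recordings, if requested

    def __post_init__(self) -> None:
        probed = self.trials["probed"].to_numpy(dtype=bool)
        ratings = self.trials["rating"].to_numpy()
        if not np.array_equal(
            ratings[probed].astype(int), self.truth.ratings[probed]
        ):
            raise ValueError("probed-trial ratings must equal the latent ratings")
        times = [ev.time for ev in self.recording.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")


def make_probe_schedule(
    n_trials: int, probe_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Pseudorandom probe trial indices with no two probes adjacent."""
    n_probes = int(round(probe_fraction * n_trials))
    n_probes = max(1, min(n_probes, (n_trials + 1) // 2))
    for _ in range(1000):
        order = rng.permutation(n_trials)
        chosen: list[int] = []
        taken = np.zeros(n_trials + 2, dtype=bool)
        for i in order:
            if not (taken[i] or taken[i + 1] or taken[i + 2]):
                taken[i + 1] = True
                chosen.append(int(i))
                if len(chosen) == n_probes:
                    return np.sort(np.array(chosen))
    raise RuntimeError("could not build a non-adjacent probe schedule")


def _validate_probes(probe_indices: Sequence[int], n_trials: int) -> np.ndarray:
    probes = np.sort(np.asarray(probe_indices, dtype=int))
    if probes.size and (probes[0] < 0 or probes[-1] >= n_trials):
        raise ValueError("probe index outside the session")
    if np.any(np.diff(probes) < 2):
        raise ValueError("probe schedule error: two probes on adjacent trials")
    return probes


def make_state_trajectory(
    n_trials: int,
    probe_indices: Sequence[int],
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> LatentStateTrajectory:
    """First-order Markov drift on rating levels with post-probe reset.

    Each trial the rating moves one level toward OFF (level 1) with
    probability ``config.drift_rate``.  The trial after a probe resets
    toward ON: the rating becomes ``max(current, draw from {4, 5})``,
    reflecting that probes interrupt mind-wandering.
    """
    probes = _validate_probes(probe_indices, n_trials)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    probe_set = set(probes.tolist())
    ratings = np.empty(n_trials, dtype=int)
    r = config.start_rating
    for t in range(n_trials):
        if t > 0:
            if (t - 1) in probe_set:
                r = max(r, int(rng.integers(4, 6)))
            elif rng.random() < config.drift_rate:
                r = max(1, r - 1)
        ratings[t] = r
    return LatentStateTrajectory(ratings=ratings)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def logistic_accuracy(x: float, params: tuple[float, float, float, float]) -> float:
    a, b, c, d = params
    p = a + (b - a) / (1.0 + math.exp(-(c * x + d)))
    return min(1.0, max(0.0, p))


def simulate_behavior(
    state_label: str,
    tilt_angle: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    psych_shift: float = 0.0,
    rt_mean_offset: float = 0.0,
) -> tuple[bool, float]:
    """Draw (correct, RT seconds) for one trial.

    Accuracy follows the state-specific logistic of |tilt|; RT is a shifted
    lognormal with state-specific mean and sd (OFF slower and more
    variable).  ``psych_shift`` and ``rt_mean_offset`` carry per-subject
    jitter.  Degenerate parameters clamp probabilities to [0, 1].
    """
    x = abs(float(tilt_angle))
    if not any(math.isclose(x, a, abs_tol=1e-6) for a in PARADIGM_ANGLES):
        raise ValueError(f"|tilt| {x} not in the paradigm set {PARADIGM_ANGLES}")
    a, b, c, d = config.psychometric_params[state_label]
    p = logistic_accuracy(x, (a, b, c, d + psych_shift * -c))
    correct = bool(rng.random() < p)
    mean, sd = config.rt_params[state_label]
    mean = max(0.05, mean + rt_mean_offset)
    mu, sigma = _lognormal_params(mean - config.rt_shift, sd)
    rt = config.rt_shift + float(rng.lognormal(mu, sigma))
    return correct, rt


# ---------------------------------------------------------------------------
# Evoked component templates


def _raised_cosine(t: np.ndarray, t0: float, tp: float, t1: float) -> np.ndarray:
    """Smooth unit-peak window: cosine rise t0->tp, cosine fall tp->t1."""
    w = np.zeros_like(t)
    rise = (t >= t0) & (t <= tp)
    fall = (t > tp) & (t <= t1)
    w[rise] = 0.5 * (1.0 - np.cos(np.pi * (t[rise] - t0) / (tp - t0)))
    w[fall] = 0.5 * (1.0 + np.cos(np.pi * (t[fall] - tp) / (t1 - tp)))
    return w


def c1_template(config: SimulationConfig, t_post: np.ndarray) -> np.ndarray:
    """Unit-amplitude C1-like deflection (symmetric about its peak)."""
    t1 = config.c1_peak + (config.c1_peak - config.c1_onset)
    return _raised_cosine(t_post, config.c1_onset, config.c1_peak, t1)


def bha_envelope_template(config: SimulationConfig, t_post: np.ndarray) -> np.ndarray:
    """Unit-peak amplitude window of the evoked high-frequency burst."""
    return _raised_cosine(
        t_post, config.bha_window[0], config.bha_peak_time, config.bha_window[1]
    )


def _theta_power_factor(rating: int, gain: float) -> float:
    """Theta power multiplier per rating level.

    Power is state-class driven (OFF: gain, MID: sqrt(gain), ON: 1) with a
    small within-class tweak (±3%) so the five levels remain separable while
    the OFF/ON power ratio stays within a few percent of ``gain``.
    """
    base = {"OFF": gain, "MID": math.sqrt(gain), "ON": 1.0}[rating_to_state(rating)]
    tweak = {1: 1.03, 2: 0.97, 3: 1.0, 4: 1.03, 5: 0.97}[rating]
    return base * tweak


def _tilt_scale(tilt: float) -> float:
    """Logistic scaling of burst amplitude with unsigned tilt angle."""
    return 0.5 + 0.5 / (1.0 + math.exp(-(abs(tilt) - 6.0) / 2.0))


def generate_session(
    config: SimulationConfig, return_components: bool = False
) -> SyntheticSession:
    """Generate a full synthetic session.

    The recording is the additive sum of background Gaussian noise, a
    per-trial theta oscillation whose power tracks the latent rating, an
    evoked band-limited high-frequency burst scaled by |tilt| and state, and
    a C1-like deflection whose sign flips with the visual field.  Evoked
    components are injected into the occipital channel group only; noise is
    everywhere.  With ``return_components=True`` the per-component arrays
    are retained for template-recovery tests.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    (s_sched, s_state, s_tilt, s_beh, s_noise, s_carrier, s_phase, s_subj) = [
        np.random.default_rng(s) for s in root.spawn(8)
    ]

    fs = cfg.sampling_rate
    n_samp_trial = int(round(cfg.trial_duration * fs))
    n_samp = cfg.n_trials * n_samp_trial + int(round(fs))  # 1 s tail padding
    n_occ = cfg.occipital_channels

    probes = make_probe_schedule(cfg.n_trials, cfg.probe_fraction, s_sched)
    truth = make_state_trajectory(cfg.n_trials, probes, cfg, s_state)
    labels = truth.labels

    tilts = s_tilt.choice(PARADIGM_ANGLES, size=cfg.n_trials) * s_tilt.choice(
        [-1.0, 1.0], size=cfg.n_trials
    )
    vfields = np.where(s_tilt.random(cfg.n_trials) < 0.5, "UVF", "LVF")

    # per-session (subject-level) jitter
    psych_shift = float(s_subj.normal(0.0, cfg.psych_shift_jitter_sd))
    rt_offset = float(s_subj.normal(0.0, cfg.rt_mean_jitter_sd))
    response_gain = float(np.exp(s_subj.normal(0.0, cfg.response_gain_jitter_sd)))

    # signal containers
    noise = (
        s_noise.normal(0.0, cfg.noise_sd, size=(cfg.n_channels, n_samp))
        if cfg.noise_sd > 0
        else np.zeros((cfg.n_channels, n_samp))
    )
    theta = np.zeros((cfg.n_channels, n_samp))
    bha = np.zeros((cfg.n_channels, n_samp))
    c1 = np.zeros((cfg.n_channels, n_samp))

    # band-limited unit-variance carrier for the high-frequency burst
    white = s_carrier.normal(0.0, 1.0, size=(n_occ, n_samp))
    sos = signal.butter(4, list(cfg.bha_band), btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfiltfilt(sos, white, axis=1)
    carrier /= carrier.std(axis=1, keepdims=True)

    t_trial = np.arange(n_samp_trial) / fs  # time within trial
    t_post = t_trial - cfg.pre_stim  # time relative to stimulus onset
    c1_shape = c1_template(cfg, t_post)
    bha_shape = bha_envelope_template(cfg, t_post)
    if cfg.bha_state_gain_window is not None:
        gw0, gw1 = cfg.bha_state_gain_window
        gain_mask = (t_post >= gw0) & (t_post < gw1)
    else:
        gain_mask = np.ones_like(t_post, dtype=bool)

    events: list[Event] = []
    rows = []
    probe_set = set(probes.tolist())

    for i in range(cfg.n_trials):
        i0 = i * n_samp_trial
        sl = slice(i0, i0 + n_samp_trial)
        onset = (i0 + int(round(cfg.pre_stim * fs))) / fs
        rating = int(truth.ratings[i])
        state = labels[i]

        # theta over the whole trial, amplitude from the rating level
        phase = s_phase.random() * 2 * np.pi
        amp = cfg.theta_amp * math.sqrt(_theta_power_factor(rating, cfg.theta_state_gain))
        theta_wave = amp * np.sin(2 * np.pi * cfg.theta_freq * t_trial + phase)
        theta[:n_occ, sl] += theta_wave[None, :]

        # evoked high-frequency burst: windowed band-limited noise
        state_gain = cfg.bha_gain_by_state[state]
        gains = np.where(gain_mask, state_gain, 1.0)
        env = response_gain * cfg.bha_amp * _tilt_scale(tilts[i]) * bha_shape * gains
        bha[:n_occ, sl] += carrier[:, sl] * env[None, :]

        # C1 deflection, polarity by visual field
        sign = -1.0 if vfields[i] == "UVF" else 1.0
        c1[:n_occ, sl] += sign * response_gain * cfg.c1_amp * c1_shape[None, :]

        correct, rt = simulate_behavior(
            state, tilts[i], cfg, s_beh, psych_shift=psych_shift, rt_mean_offset=rt_offset
        )
        probed = i in probe_set
        events.append(
            Event(
                time=onset,
                kind="stimulus",
                payload={
                    "trial": i,
                    "tilt": float(tilts[i]),
                    "visual_field": str(vfields[i]),
                    "probed": bool(probed),
                    "rating": rating if probed else np.nan,
                    "state_true": state,
                    "correct": bool(correct),
                    "rt": float(rt),
                },
            )
        )
        if probed:
            events.append(Event(time=onset + cfg.trial_duration * 0.75, kind="probe",
                                payload={"trial": i, "rating": rating}))
        rows.append(
            {
                "trial": i,
                "onset_time": onset,
                "tilt": float(tilts[i]),
                "visual_field": str(vfields[i]),
                "probed": bool(probed),
                "rating": float(rating) if probed else np.nan,
                "rating_true": rating,
                "state_true": state,
                "correct": bool(correct),
                "rt": float(rt),
            }
        )

    data = noise + theta + bha + c1
    labels_ch = [f"OCC{j}" if j < n_occ else f"CH{j}" for j in range(cfg.n_channels)]
    rec = Recording(
        data=data,
        sampling_rate=fs,
        channel_labels=labels_ch,
        events=sorted(events, key=lambda e: e.time),
        channel_groups={"occipital": labels_ch[:n_occ]},
    )
    trials = pd.DataFrame(rows)
    trials["position_from_probe"] = _positions_from_probe(trials["probed"].to_numpy())
    components = (
        {"noise": noise, "theta": theta, "bha": bha, "c1": c1} if return_components else None
    )
    return SyntheticSession(
        recording=rec, trials=trials, truth=truth, config=cfg, components=components
    )


def _positions_from_probe(probed: np.ndarray) -> np.ndarray:
    """Distance N of each trial from the preceding probe (FQ+N); NaN before
    the first probe and for probe trials themselves."""
    pos = np.full(probed.size, np.nan)
    last = None
    for i, p in enumerate(probed):
        if last is not None and not p:
            pos[i] = i - last
        if p:
            last = i
    return pos


def generate_cohort(
    config: SimulationConfig, n_subjects: int, seed: int | None = None
) -> list[SyntheticSession]:
    """Independent sessions for ``n_subjects``, seeds derived from ``seed``."""
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    subject_seeds = ss.generate_state(n_subjects) % (2**31 - 1)
    return [
        generate_session(replace(config, seed=int(s))) for s in subject_seeds
    ]
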