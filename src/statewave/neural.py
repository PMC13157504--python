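"""Stimulus-evoked neural response characterization.

Broadband high-frequency activity (BHA) is the Hilbert amplitude envelope
of the 80–150 Hz band-passed signal; after per-trial baseline z-scoring,
channels whose trial-averaged envelope exceeds z > 3 for at least 100 ms
post-stimulus count as stimulus responsive.  The group response window
comes from a circular-shift surrogate; orientation (supra vs sub threshold)
and state (ON vs OFF) contrasts are permutation-tested, with separate
rising-flank (50–122 ms) and falling-flank (122–288 ms) comparisons.  The
C1 — the earliest visual evoked deflection, polarity flipping between
upper and lower visual field — is collapsed across fields and compared to
the BHA in onset and peak latency, including a time-resolved correlation
of the C1 peak amplitude with the BHA envelope against a subject
reassignment null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocessing import Epochs
from .stats import (
    SurrogateDistribution,
    TestResult,
    circular_shift_surrogate,
    fdr_bh,
    paired_t,
    surrogate_p,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseWindow",
    "LatencyStats",
    "stimulus_responsive_channels",
    "response_window_circshift",
    "orientation_contrast",
    "state_contrast_timecourse",
    "flank_contrast",
    "collapse_c1",
    "onset_and_peak",
    "c1_bha_correlation",
]


@dataclass
class ResponseWindow:
    """Detected significant response window, times in ms post-stimulus."""

    onset_ms: float
    offset_ms: float
    peak_time_ms: float
    peak_value: float
    significant: np.ndarray  # boolean mask over time points
    q: np.ndarray  # FDR-adjusted pointwise p


@dataclass
class LatencyStats:
    c1_onset_ms: np.ndarray  # per subject
    c1_peak_ms: np.ndarray
    bha_onset_ms: np.ndarray
    bha_peak_ms: np.ndarray
    onset_t: TestResult
    peak_t: TestResult
    onset_r: TestResult
    peak_r: TestResult


def stimulus_responsive_channels(
    env: Epochs, z_thresh: float = 3.0, min_duration: float = 0.1
) -> list[str]:
    """Channels whose trial-averaged z-scored envelope stays above
    ``z_thresh`` for at least ``min_duration`` seconds post-stimulus.

    Contiguity is strict: consecutive samples above threshold, no gap
    tolerance.  Requires z-scored input.
    """
    if env.baseline_state != "z_scored":
        raise ValueError("stimulus_responsive_channels needs z-scored envelope epochs")
    mean = env.data.mean(axis=0)  # (n_channels, n_samples)
    post = env.times >= 0
    need = int(round(min_duration * env.sampling_rate))
    selected = []
    for ci, label in enumerate(env.channel_labels):
        above = mean[ci, post] > z_thresh
        if _longest_run(above) >= need:
            selected.append(label)
    return selected


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs of True runs."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask) - 1))
    return out


def response_window_circshift(
    series: np.ndarray,
    times: np.ndarray,
    n_iter: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    shift_range: tuple[int, int] | None = None,
) -> tuple[ResponseWindow | None, np.ndarray]:
    """Significant amplitude-modulation window of a group-mean time series.

    ``series`` is per-subject (n_subjects, n_times).  The null is built by
    circularly shifting each subject's series by independent offsets in
    ``n_iter`` iterations and recomputing the group mean; pointwise p
    (one-sided, amplitude above the null) are FDR corrected across time
    points.  Returns the widest significant post-stimulus window (onset,
    offset, peak) or None, plus the q-value series.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 2:
        raise ValueError("series must be (n_subjects >= 2, n_times)")
    dist = circular_shift_surrogate(
        series,
        statistic=lambda s: s.mean(axis=0),
        n_iter=n_iter,
        shift_range=shift_range,
        seed=seed,
    )
    p = dist.p
    if np.allclose(dist.null_values.std(axis=0), 0.0):
        # shifts of a constant series are identical: degenerate null
        return None, np.ones_like(p)
    q = fdr_bh(p)
    sig = (q < alpha) & (times >= 0)
    runs = _runs(sig)
    if not runs:
        return None, q
    start, end = max(runs, key=lambda r: r[1] - r[0])
    mean = series.mean(axis=0)
    peak_rel = int(np.argmax(mean[start : end + 1]))
    window = ResponseWindow(
        onset_ms=float(times[start] * 1000),
        offset_ms=float(times[end] * 1000),
        peak_time_ms=float(times[start + peak_rel] * 1000),
        peak_value=float(mean[start + peak_rel]),
        significant=sig,
        q=q,
    )
    return window, q


def orientation_contrast(
    supra: np.ndarray,
    sub: np.ndarray,
    tails: str = "one",
) -> TestResult:
    """Paired t of window-averaged envelope, supra- vs sub-threshold trials.

    Inputs are per-subject window means; the directed variant tests
    supra > sub (the stated hypothesis direction).
    """
    supra = np.asarray(supra, dtype=float)
    sub = np.asarray(sub, dtype=float)
    if supra.size == 0 or sub.size == 0:
        raise ValueError("both orientation groups must be non-empty")
    return paired_t(supra, sub, tails=tails)


def state_contrast_timecourse(
    env_on: np.ndarray,
    env_off: np.ndarray,
    times: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict:
    """Time-resolved ON vs OFF paired t against a label-permutation null.

    ``env_on``/``env_off`` are per-subject mean envelope series
    (n_subjects, n_times).  The null reassigns the ON/OFF labels within
    subject (sign flips of the paired differences) in ``n_perm``
    permutations; pointwise two-sided p are FDR corrected across time and
    significant intervals reported.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a = np.asarray(env_on, dtype=float)
    b = np.asarray(env_off, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("conditions must be (n_subjects >= 2, n_times) and matching")
    d = a - b
    n_sub = d.shape[0]

    def _t(dd: np.ndarray) -> np.ndarray:
        sd = dd.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = dd.mean(axis=0) / (sd / np.sqrt(n_sub))
        return np.where(sd > 0, t, 0.0)

    t_obs = _t(d)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, d.shape[1]))
    for it in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_sub)
        null[it] = _t(d * signs[:, None])
    p = surrogate_p(np.abs(t_obs), np.abs(null))
    q = fdr_bh(p)
    sig = q < alpha
    intervals = [
        (float(times[s] * 1000), float(times[e] * 1000)) for s, e in _runs(sig)
    ]
    return {"t": t_obs, "p": p, "q": q, "significant": sig, "intervals_ms": intervals}


def flank_contrast(
    env_on: np.ndarray,
    env_off: np.ndarray,
    times: np.ndarray,
    rising: tuple[float, float] = (0.050, 0.122),
    falling: tuple[float, float] = (0.122, 0.288),
    n_perm: int = 1000,
    seed: int | None = None,
    tails: str = "one",
) -> dict:
    """ON vs OFF contrast of the rising and falling burst flanks.

    Window means per subject are compared with a paired t whose p comes
    from a within-subject label-permutation (sign-flip) null; the directed
    variant tests ON > OFF.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    out = {}
    rng = np.random.default_rng(seed)
    for name, (w0, w1) in (("rising", rising), ("falling", falling)):
        if w0 < times[0] or w1 > times[-1] + 1e-9:
            raise ValueError(f"{name} window outside the epoch")
        m = (times >= w0 - 1e-12) & (times < w1 - 1e-12)
        a = np.asarray(env_on)[:, m].mean(axis=1)
        b = np.asarray(env_off)[:, m].mean(axis=1)
        d = a - b
        n_sub = d.size
        sd = d.std(ddof=1)
        t_obs = 0.0 if sd == 0 else float(d.mean() / (sd / np.sqrt(n_sub)))
        null = np.empty(n_perm)
        for it in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n_sub)
            ds = d * signs
            sds = ds.std(ddof=1)
            null[it] = 0.0 if sds == 0 else ds.mean() / (sds / np.sqrt(n_sub))
        if tails == "one":
            p = float(surrogate_p(np.asarray(t_obs), null))
        else:
            p = float(surrogate_p(np.asarray(abs(t_obs)), np.abs(null)))
        out[name] = TestResult(t_obs, p, df=(float(n_sub - 1),), tails=tails, label=name)
    return out


def collapse_c1(erp_uvf: Epochs | None, erp_lvf: Epochs | None) -> np.ndarray:
    """Collapse the C1 across visual fields into one positive-going series.

    The upper-visual-field response (negative-going C1) is sign-flipped and
    averaged with the lower-visual-field response, averaging channels and
    trials; returns the (n_samples,) group series.
    """
    if erp_uvf is None or erp_lvf is None:
        raise ValueError("both visual fields are required to collapse the C1")
    if erp_uvf.n_trials == 0 or erp_lvf.n_trials == 0:
        raise ValueError("both visual fields need at least one trial")
    uvf = erp_uvf.data.mean(axis=(0, 1))
    lvf = erp_lvf.data.mean(axis=(0, 1))
    return 0.5 * (-uvf + lvf)


def onset_and_peak(
    z_series: np.ndarray, times: np.ndarray, z_thresh: float = 3.0
) -> tuple[float, float, float]:
    """Onset, peak time and peak value of a z-scored response series.

    Onset is the first post-stimulus crossing of ``z_thresh``; the peak is
    the maximum within the contiguous supra-threshold window starting at
    the onset.  Raises if the series never crosses (caller excludes the
    subject and logs).  Times returned in ms.
    """
    z = np.asarray(z_series, dtype=float)
    post = times >= 0
    above = z > z_thresh
    idx_post = np.flatnonzero(post & above)
    if idx_post.size == 0:
        raise ValueError("series never exceeds the threshold post-stimulus")
    i0 = idx_post[0]
    i1 = i0
    while i1 + 1 < z.size and above[i1 + 1]:
        i1 += 1
    seg = z[i0 : i1 + 1]
    ip = i0 + int(np.argmax(seg))
    return float(times[i0] * 1000), float(times[ip] * 1000), float(z[ip])


def latency_comparison(
    c1_series: np.ndarray,
    bha_series: np.ndarray,
    times: np.ndarray,
    z_thresh: float = 3.0,
) -> LatencyStats:
    """Per-subject C1 vs BHA onset/peak latencies with paired t and Pearson r.

    Subjects whose C1 or BHA never crosses the threshold are excluded and
    logged.
    """
    from .stats import correlation

    c1_on, c1_pk, bha_on, bha_pk = [], [], [], []
    excluded = 0
    for cs, bs in zip(np.asarray(c1_series), np.asarray(bha_series)):
        try:
            co, cp, _ = onset_and_peak(cs, times, z_thresh)
            bo, bp, _ = onset_and_peak(bs, times, z_thresh)
        except ValueError:
            excluded += 1
            continue
        c1_on.append(co)
        c1_pk.append(cp)
        bha_on.append(bo)
        bha_pk.append(bp)
    if excluded:
        logger.info("latency_comparison: excluded %d subject(s) without onsets", excluded)
    if len(c1_on) < 3:
        raise ValueError("fewer than 3 subjects with defined onsets")
    return LatencyStats(
        c1_onset_ms=np.asarray(c1_on),
        c1_peak_ms=np.asarray(c1_pk),
        bha_onset_ms=np.asarray(bha_on),
        bha_peak_ms=np.asarray(bha_pk),
        onset_t=paired_t(bha_on, c1_on),
        peak_t=paired_t(bha_pk, c1_pk),
        onset_r=correlation(c1_on, bha_on),
        peak_r=correlation(c1_pk, bha_pk),
    )


def c1_bha_correlation(
    c1_peak_amp: np.ndarray,
    bha_series: np.ndarray,
    times: np.ndarray,
    n_iter: int = 1000,
    ci: float = 0.99,
    seed: int | None = None,
) -> dict:
    """Time-resolved Pearson r of the C1 peak amplitude with the BHA.

    ``c1_peak_amp`` is (n_subjects,), ``bha_series`` (n_subjects, n_times).
    The critical value is the ``ci`` quantile of a null built by randomly
    reassigning the C1 values to subjects at the time of the maximum
    observed correlation; intervals where r exceeds it are significant.
    """
    c1 = np.asarray(c1_peak_amp, dtype=float)
    bha = np.asarray(bha_series, dtype=float)
    if c1.size < 5:
        raise ValueError("need >= 5 subjects")
    if bha.shape[0] != c1.size:
        raise ValueError("subject dimension mismatch")
    c1c = c1 - c1.mean()
    bc = bha - bha.mean(axis=0)
    denom = np.sqrt((c1c**2).sum()) * np.sqrt((bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_t = (c1c @ bc) / denom
    r_t = np.where(denom > 0, r_t, 0.0)
    i_max = int(np.nanargmax(r_t))

    rng = np.random.default_rng(seed)
    y = bha[:, i_max]
    yc = y - y.mean()
    ynorm = np.sqrt((yc**2).sum())
    null = np.empty(n_iter)
    for it in range(n_iter):
        perm = rng.permutation(c1c)
        null[it] = (perm @ yc) / (np.sqrt((perm**2).sum()) * ynorm)
    r_crit = float(np.quantile(null, ci))
    sig = r_t > r_crit
    intervals = [
        (float(times[s] * 1000), float(times[e] * 1000)) for s, e in _runs(sig)
    ]
    return {
        "r": r_t,
        "r_crit": r_crit,
        "r_max": float(r_t[i_max]),
        "t_max_ms": float(times[i_max] * 1000),
        "significant": sig,
        "intervals_ms": intervals,
        "null": null,
    }
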