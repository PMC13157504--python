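"""BHA response characterization, C1 collapse, latency statistics."""

import numpy as np
import pandas as pd
import pytest

from statewave import neural as neu
from statewave.preprocessing import Epochs


FS = 500.0
TIMES = -0.3 + np.arange(500) / FS  # (-0.3, 0.7) epoch


def make_env_epochs(data, baseline_state="z_scored"):
    n = data.shape[0]
    return Epochs(
        data=data,
        window=(-0.3, 0.7),
        sampling_rate=FS,
        channel_labels=[f"c{i}" for i in range(data.shape[1])],
        metadata=pd.DataFrame({"event_time": np.arange(n, dtype=float)}),
        baseline_state=baseline_state,
    )


def bump(times, t0, t1, amp):
    w = np.zeros_like(times)
    m = (times >= t0) & (times <= t1)
    w[m] = amp * np.sin(np.pi * (times[m] - t0) / (t1 - t0))
    return w


# ---------------------------------------------------------------------------
# Channel selection


def test_plateau_channel_selected(rng):
    data = rng.normal(0, 1, (30, 2, 500))
    plateau = ((TIMES >= 0.1) & (TIMES < 0.25)).astype(float) * 5.0  # 150 ms at z=5
    data[:, 0, :] += plateau
    sel = neu.stimulus_responsive_channels(make_env_epochs(data))
    assert sel == ["c0"]


def test_short_plateau_not_selected(rng):
    data = rng.normal(0, 0.1, (30, 1, 500))
    plateau = ((TIMES >= 0.1) & (TIMES < 0.15)).astype(float) * 5.0  # only 50 ms
    data[:, 0, :] += plateau
    assert neu.stimulus_responsive_channels(make_env_epochs(data)) == []


def test_non_zscored_input_rejected(rng):
    data = rng.normal(0, 1, (5, 1, 500))
    with pytest.raises(ValueError):
        neu.stimulus_responsive_channels(make_env_epochs(data, baseline_state="raw"))


def test_noise_channel_selection_rate_below_half_percent(rng):
    # trial-averaged pure noise essentially never sustains z > 3 for 100 ms
    data = rng.normal(0, 1, (40, 400, 500))
    sel = neu.stimulus_responsive_channels(make_env_epochs(data))
    assert len(sel) / 400 < 0.005


# ---------------------------------------------------------------------------
# Response window (circular shift)


def test_constant_series_yields_no_window():
    series = np.tile(np.linspace(1, 2, 5)[:, None], (1, 500))
    window, q = neu.response_window_circshift(series * 0 + 1.0, TIMES, n_iter=200, seed=0)
    assert window is None


def test_injected_bump_window_recovered(rng):
    overlaps = []
    plateau = np.where((TIMES >= 0.10) & (TIMES < 0.20), 5.0, 0.0)  # z=5 for 100 ms
    for seed in range(10):
        r = np.random.default_rng(seed)
        series = r.normal(0, 1, (12, 500)) + plateau
        window, _ = neu.response_window_circshift(series, TIMES, n_iter=400, seed=seed)
        if window is None:
            overlaps.append(0.0)
            continue
        lo, hi = max(window.onset_ms, 100), min(window.offset_ms, 200)
        overlaps.append(max(0.0, hi - lo) / 100.0)
    assert np.median(overlaps) >= 0.8


def test_stationary_noise_rarely_significant(rng):
    hits = 0
    for seed in range(10):
        r = np.random.default_rng(100 + seed)
        series = r.normal(0, 1, (10, 500))
        window, _ = neu.response_window_circshift(series, TIMES, n_iter=300, seed=seed)
        hits += window is not None
    assert hits <= 2


# ---------------------------------------------------------------------------
# Contrasts


def test_orientation_contrast_identical_groups_t_zero():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = neu.orientation_contrast(x, x.copy(), tails="two")
    assert res.statistic == pytest.approx(0.0)


def test_orientation_contrast_sign_flips_on_group_swap(rng):
    a = rng.normal(1, 0.3, 10)
    b = rng.normal(0.5, 0.3, 10)
    r1 = neu.orientation_contrast(a, b, tails="two")
    r2 = neu.orientation_contrast(b, a, tails="two")
    assert r1.statistic == pytest.approx(-r2.statistic)


def test_state_contrast_nperm_guard(rng):
    x = rng.normal(0, 1, (4, 100))
    with pytest.raises(ValueError):
        neu.state_contrast_timecourse(x, x, TIMES[:100], n_perm=1)


def test_state_contrast_null_rarely_significant():
    hits = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        on = r.normal(0, 1, (10, 200))
        off = r.normal(0, 1, (10, 200))
        out = neu.state_contrast_timecourse(on, off, TIMES[:200], n_perm=200, seed=seed)
        hits += bool(out["intervals_ms"])
    assert hits <= 2


def test_state_contrast_detects_interval_where_injected(rng):
    on = rng.normal(0, 0.5, (14, 500)) + bump(TIMES, 0.10, 0.20, 2.0)
    off = rng.normal(0, 0.5, (14, 500))
    out = neu.state_contrast_timecourse(on, off, TIMES, n_perm=300, seed=1)
    assert out["intervals_ms"]
    # the dominant detected interval lies inside the injected region
    lo, hi = max(out["intervals_ms"], key=lambda iv: iv[1] - iv[0])
    assert lo >= 80 and hi <= 220


def test_flank_contrast_swapped_windows_swap_results(rng):
    on = rng.normal(1, 0.2, (10, 500))
    off = rng.normal(0.8, 0.2, (10, 500))
    a = neu.flank_contrast(on, off, TIMES, n_perm=150, seed=0)
    b = neu.flank_contrast(
        on, off, TIMES, rising=(0.122, 0.288), falling=(0.050, 0.122), n_perm=150, seed=0
    )
    assert a["rising"].statistic == pytest.approx(b["falling"].statistic)
    assert a["falling"].statistic == pytest.approx(b["rising"].statistic)


# ---------------------------------------------------------------------------
# C1


def test_collapse_c1_exact_mirror_returns_lvf(rng):
    lvf_data = rng.normal(0, 1, (6, 2, 500))
    uvf = make_env_epochs(-lvf_data, baseline_state="raw")
    lvf = make_env_epochs(lvf_data, baseline_state="raw")
    collapsed = neu.collapse_c1(uvf, lvf)
    assert collapsed == pytest.approx(lvf_data.mean(axis=(0, 1)))


def test_collapse_c1_requires_both_fields(rng):
    lvf = make_env_epochs(rng.normal(0, 1, (3, 1, 500)), baseline_state="raw")
    with pytest.raises(ValueError):
        neu.collapse_c1(None, lvf)


def test_collapse_c1_template_amplitude(rng):
    template = bump(TIMES, 0.046, 0.09, 2.5)
    uvf = make_env_epochs(np.tile(-template, (4, 1, 1)), baseline_state="raw")
    lvf = make_env_epochs(np.tile(template, (4, 1, 1)), baseline_state="raw")
    collapsed = neu.collapse_c1(uvf, lvf)
    assert collapsed.max() == pytest.approx(2.5, rel=1e-6)


# ---------------------------------------------------------------------------
# Onset / peak latency


def test_onset_at_step_crossing():
    z = np.where(TIMES >= 0.06, 5.0, 0.0)
    onset, peak, val = neu.onset_and_peak(z, TIMES)
    assert onset == pytest.approx(60.0, abs=2.0)
    assert val == 5.0


def test_onset_undefined_when_never_crossing():
    with pytest.raises(ValueError):
        neu.onset_and_peak(np.ones(500), TIMES)


def test_c1_before_bha_ordering_recovered(rng):
    c1_stack, bha_stack = [], []
    for s in range(12):
        c1_stack.append(bump(TIMES, 0.046, 0.09, 20.0) + rng.normal(0, 0.5, 500))
        bha_stack.append(bump(TIMES, 0.05, 0.288, 8.0) + rng.normal(0, 0.5, 500))
    lat = neu.latency_comparison(np.vstack(c1_stack), np.vstack(bha_stack), TIMES)
    assert lat.c1_onset_ms.mean() < lat.bha_onset_ms.mean()
    assert lat.c1_peak_ms.mean() < lat.bha_peak_ms.mean()
    assert lat.peak_t.p < 0.05


# ---------------------------------------------------------------------------
# C1–BHA correlation


def test_broadcast_bha_gives_perfect_correlation(rng):
    amps = rng.normal(5, 1, 10)
    bha = np.tile(amps[:, None], (1, 200))
    out = neu.c1_bha_correlation(amps, bha, TIMES[:200], n_iter=200, seed=0)
    assert out["r"] == pytest.approx(np.ones(200))
    assert np.all(out["significant"])


def test_independent_draws_exceedance_near_one_percent():
    exceed = []
    for seed in range(60):
        r = np.random.default_rng(seed)
        amps = r.normal(0, 1, 12)
        bha = r.normal(0, 1, (12, 30))
        out = neu.c1_bha_correlation(amps, bha, TIMES[:30], n_iter=300, seed=seed)
        # drop the max-time point: the critical value is anchored there
        mask = np.ones(30, bool)
        mask[np.argmax(out["r"])] = False
        exceed.append(out["significant"][mask].mean())
    assert np.mean(exceed) < 0.05


def test_shared_latent_amplitude_detected_at_injection_time(rng):
    hits = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        latent = r.normal(0, 1, 20)
        amps = latent + r.normal(0, 0.6, 20)
        bha = r.normal(0, 1, (20, 100))
        inject = int(np.argmin(np.abs(TIMES[:100] * 1000 - 160)))
        bha[:, inject] = latent + r.normal(0, 0.6, 20)
        out = neu.c1_bha_correlation(amps, bha, TIMES[:100], n_iter=300, seed=seed)
        t_inj = TIMES[inject] * 1000
        hits += any(lo <= t_inj <= hi for lo, hi in out["intervals_ms"])
    assert hits >= 8


def test_too_few_subjects_rejected(rng):
    with pytest.raises(ValueError):
        neu.c1_bha_correlation(rng.normal(0, 1, 4), rng.normal(0, 1, (4, 50)), TIMES[:50])
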