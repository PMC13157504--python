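"""State-evolution dynamics after thought probes.

A thought probe (focus query, FQ) reports the attentional rating of the
trial it follows; the trials after it (FQ+1 … FQ+N) carry decoded labels
only.  This module tests (i) whether probes interrupt mind-wandering —
OFF likelihood drops from FQ to FQ+1 (a 2-way ANOVA against a surrogate
built from randomly chosen trials), (ii) how the ON/OFF likelihoods evolve
with trials since the probe (Pearson r against a label-shuffle surrogate,
a per-subject z-scored composite measure, pairwise FQ+1 vs FQ+N t-tests
with FDR), and (iii) a Spearman variant on ratings grouped by distance
from an ON report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats
from .stats import TestResult, anova_f, fdr_bh, paired_t
from .synthetic import rating_to_state

logger = logging.getLogger(__name__)

__all__ = [
    "StateSeries",
    "EvolutionResult",
    "category_likelihoods",
    "probe_interruption_test",
    "evolution_composite",
    "spearman_rating_drift",
    "evolution_span_seconds",
    "on_report_distances",
]


def category_likelihoods(labels: Sequence[int]) -> dict:
    """Proportion of each rating level (1–5) and of the grouped states.

    OFF = ratings {1, 2}, MID = {3}, ON = {4, 5}.
    """
    r = np.asarray(labels, dtype=int)
    if r.size == 0:
        raise ValueError("empty label list")
    if np.any((r < 1) | (r > 5)):
        raise ValueError("labels must be ratings 1..5")
    per = np.array([(r == lev).mean() for lev in (1, 2, 3, 4, 5)])
    return {
        "per_rating": per,
        "OFF": float(per[0] + per[1]),
        "MID": float(per[2]),
        "ON": float(per[3] + per[4]),
    }


def evolution_span_seconds(n_max: int = 25, trial_duration: float = 2.0) -> float:
    """Temporal span covered by the post-probe positions FQ+1 … FQ+n_max."""
    if n_max < 1 or trial_duration <= 0:
        raise ValueError("need n_max >= 1 and a positive trial duration")
    return n_max * trial_duration


# ---------------------------------------------------------------------------
# Probe interruption


def probe_interruption_test(
    fq_ratings: Sequence[Sequence[int]],
    fq1_predicted: Sequence[Sequence[int]],
    all_predicted: Sequence[Sequence[int]],
    n_iter: int = 1000,
    seed: int | None = None,
) -> dict:
    """Does the probe interrupt mind-wandering?

    Per subject, OFF and ON likelihoods are computed for FQ trials (reported
    ratings) and FQ+1 trials (predicted ratings) and compared in a 2-way
    ANOVA with factors trial type (FQ vs FQ+1) and state (OFF vs ON).  The
    observed main (trial type) and interaction F are referred to a surrogate
    distribution in which each subject's FQ+1 likelihoods are recomputed
    from as many randomly chosen trials (from ``all_predicted``) as that
    subject has FQ+1 trials.  Post-hoc paired t-tests compare FQ vs FQ+1
    separately for OFF and ON.
    """
    keep = [i for i, fq in enumerate(fq_ratings) if len(fq) > 0]
    if len(keep) < len(fq_ratings):
        logger.info(
            "probe_interruption_test: excluded %d subject(s) without FQ trials",
            len(fq_ratings) - len(keep),
        )
    fq_ratings = [np.asarray(fq_ratings[i], dtype=int) for i in keep]
    fq1_predicted = [np.asarray(fq1_predicted[i], dtype=int) for i in keep]
    all_predicted = [np.asarray(all_predicted[i], dtype=int) for i in keep]
    n_sub = len(fq_ratings)
    if n_sub < 2:
        raise ValueError("need >= 2 subjects with FQ trials")

    def _likelihoods(trial_sets: list[np.ndarray]) -> np.ndarray:
        out = np.empty((len(trial_sets), 2))  # columns OFF, ON
        for i, labs in enumerate(trial_sets):
            lik = category_likelihoods(labs)
            out[i] = (lik["OFF"], lik["ON"])
        return out

    fq_lik = _likelihoods(fq_ratings)
    fq1_lik = _likelihoods(fq1_predicted)

    def _fs(fq1_l: np.ndarray) -> tuple[float, float]:
        values = np.concatenate([fq_lik.ravel(), fq1_l.ravel()])
        trial_type = np.repeat(["FQ", "FQ1"], n_sub * 2)
        state = np.tile(["OFF", "ON"], n_sub * 2)
        res = anova_f(values, trial_type, state)
        return res["A"].statistic, res["AxB"].statistic

    f_main, f_inter = _fs(fq1_lik)

    rng = np.random.default_rng(seed)
    null_main = np.empty(n_iter)
    null_inter = np.empty(n_iter)
    for it in range(n_iter):
        surr = [
            rng.choice(all_predicted[i], size=len(fq1_predicted[i]), replace=False)
            if len(all_predicted[i]) >= len(fq1_predicted[i])
            else rng.choice(all_predicted[i], size=len(fq1_predicted[i]), replace=True)
            for i in range(n_sub)
        ]
        null_main[it], null_inter[it] = _fs(_likelihoods(surr))

    p_main = float(stats.surrogate_p(np.asarray(f_main), null_main))
    p_inter = float(stats.surrogate_p(np.asarray(f_inter), null_inter))

    post_off = paired_t(fq_lik[:, 0], fq1_lik[:, 0])
    post_on = paired_t(fq_lik[:, 1], fq1_lik[:, 1])
    return {
        "f_trial_type": TestResult(f_main, p_main, label="trial_type"),
        "f_interaction": TestResult(f_inter, p_inter, label="trial_type_x_state"),
        "posthoc_off": post_off,
        "posthoc_on": post_on,
        "fq_likelihoods": fq_lik,
        "fq1_likelihoods": fq1_lik,
        "n_subjects": n_sub,
    }


# ---------------------------------------------------------------------------
# Evolution of the ON/OFF likelihood with trials since the probe


@dataclass
class StateSeries:
    """Per-subject ON and OFF likelihoods at positions FQ+1 … FQ+n_max.

    Positions without data are NaN (missing), never zero.
    """

    positions: np.ndarray  # (n_max,) values 1..n_max
    on: np.ndarray  # (n_subjects, n_max)
    off: np.ndarray


@dataclass
class EvolutionResult:
    series: StateSeries
    composite: np.ndarray  # (n_subjects, n_max): mean of z(ON) and -z(OFF)
    r_on: TestResult
    r_off: TestResult
    pairwise: pd.DataFrame  # columns: position, t, p, q


def _position_likelihoods(
    df: pd.DataFrame, n_max: int
) -> tuple[StateSeries, list[dict]]:
    """Per-subject ON/OFF likelihoods by position, plus raw per-subject data
    (position codes and ratings) for the surrogate loops."""
    subjects = sorted(df["subject"].unique())
    on = np.full((len(subjects), n_max), np.nan)
    off = np.full((len(subjects), n_max), np.nan)
    raw = []
    for si, s in enumerate(subjects):
        sub = df[df["subject"] == s]
        pos = sub["position"].to_numpy(dtype=int)
        ratings = sub["rating"].to_numpy(dtype=int)
        ok = (pos >= 1) & (pos <= n_max)
        pos, ratings = pos[ok], ratings[ok]
        counts = np.bincount(pos - 1, minlength=n_max).astype(float)
        on_counts = np.bincount(pos - 1, weights=(ratings >= 4), minlength=n_max)
        off_counts = np.bincount(pos - 1, weights=(ratings <= 2), minlength=n_max)
        with np.errstate(invalid="ignore", divide="ignore"):
            on[si] = np.where(counts > 0, on_counts / counts, np.nan)
            off[si] = np.where(counts > 0, off_counts / counts, np.nan)
        raw.append({"pos": pos, "ratings": ratings, "counts": counts})
    return StateSeries(positions=np.arange(1, n_max + 1), on=on, off=off), raw


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = np.nanmean(x, axis=1, keepdims=True)
    sd = np.nanstd(x, axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    return np.where(sd > 0, z, 0.0)


def _composite(on: np.ndarray, off: np.ndarray) -> np.ndarray:
    """Per-subject composite: average of z(ON) and sign-reversed z(OFF)."""
    return (_zscore_rows(on) - _zscore_rows(off)) / 2.0


def _group_r(series: np.ndarray, positions: np.ndarray) -> float:
    """Pearson r of the subject-averaged series against position."""
    mean = np.nanmean(series, axis=0)
    ok = np.isfinite(mean)
    if ok.sum() < 3:
        return np.nan
    x, y = positions[ok], mean[ok]
    return float(np.corrcoef(x, y)[0, 1])


def evolution_composite(
    predictions: pd.DataFrame,
    n_max: int = 25,
    n_iter: int = 1000,
    seed: int | None = None,
) -> EvolutionResult:
    """Time course of decoded ON/OFF likelihood over FQ+1 … FQ+n_max.

    ``predictions`` needs columns ``subject``, ``position`` (trials since
    the last probe, 1-based) and ``rating`` (predicted 1–5; FQ trials
    themselves are excluded — they carry reported labels).  Group-level
    Pearson r of the ON and OFF likelihood series against position is
    referred to a within-subject label-shuffle surrogate; the per-subject
    z-scored composite (ON minus sign-reversed OFF) is compared FQ+1 vs
    FQ+N with paired t-tests whose p come from the same surrogate, FDR
    corrected across the pairwise family.
    """
    required = {"subject", "position", "rating"}
    if not required.issubset(predictions.columns):
        raise ValueError(f"predictions must have columns {sorted(required)}")
    max_avail = int(predictions["position"].max())
    if n_max > max_avail:
        logger.warning(
            "evolution_composite: n_max %d exceeds available spacing %d; truncated",
            n_max,
            max_avail,
        )
        n_max = max_avail
    series, raw = _position_likelihoods(predictions, n_max)
    n_sub = series.on.shape[0]
    for si in range(n_sub):
        if np.isfinite(series.on[si]).sum() < 2:
            raise ValueError(f"subject index {si} has < 2 positions with data")

    comp = _composite(series.on, series.off)
    r_on_obs = _group_r(series.on, series.positions.astype(float))
    r_off_obs = _group_r(series.off, series.positions.astype(float))

    def _t_series(c: np.ndarray) -> np.ndarray:
        """Paired t of composite at FQ+1 vs each FQ+N (N = 2..n_max)."""
        out = np.full(n_max - 1, np.nan)
        for j in range(1, n_max):
            a, b = c[:, 0], c[:, j]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() >= 2:
                d = a[ok] - b[ok]
                sd = d.std(ddof=1)
                out[j - 1] = 0.0 if sd == 0 else d.mean() / (sd / np.sqrt(ok.sum()))
        return out

    t_obs = _t_series(comp)

    rng = np.random.default_rng(seed)
    null_r_on = np.empty(n_iter)
    null_r_off = np.empty(n_iter)
    null_t = np.empty((n_iter, n_max - 1))
    for it in range(n_iter):
        on_s = np.full_like(series.on, np.nan)
        off_s = np.full_like(series.off, np.nan)
        for si, d in enumerate(raw):
            perm = rng.permutation(d["ratings"])
            on_counts = np.bincount(d["pos"] - 1, weights=(perm >= 4), minlength=n_max)
            off_counts = np.bincount(d["pos"] - 1, weights=(perm <= 2), minlength=n_max)
            with np.errstate(invalid="ignore", divide="ignore"):
                on_s[si] = np.where(d["counts"] > 0, on_counts / d["counts"], np.nan)
                off_s[si] = np.where(d["counts"] > 0, off_counts / d["counts"], np.nan)
        null_r_on[it] = _group_r(on_s, series.positions.astype(float))
        null_r_off[it] = _group_r(off_s, series.positions.astype(float))
        null_t[it] = _t_series(_composite(on_s, off_s))

    p_r_on = float(stats.surrogate_p(np.abs(np.asarray(r_on_obs)), np.abs(null_r_on)))
    p_r_off = float(stats.surrogate_p(np.abs(np.asarray(r_off_obs)), np.abs(null_r_off)))
    p_t = stats.surrogate_p(np.abs(t_obs), np.abs(null_t))
    q_t = fdr_bh(p_t)

    pairwise = pd.DataFrame(
        {"position": np.arange(2, n_max + 1), "t": t_obs, "p": p_t, "q": q_t}
    )
    return EvolutionResult(
        series=series,
        composite=comp,
        r_on=TestResult(r_on_obs, p_r_on, label="r_on"),
        r_off=TestResult(r_off_obs, p_r_off, label="r_off"),
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# Spearman variant: ratings by distance from an ON report


def on_report_distances(trials: pd.DataFrame) -> pd.DataFrame:
    """Pairs (distance, rating) of probed trials relative to the most recent
    preceding ON-rated probe (rating >= 4), one row per qualifying probe."""
    probed = trials[trials["probed"]].sort_values("trial")
    rows = []
    last_on = None
    for _, row in probed.iterrows():
        if last_on is not None:
            rows.append({"distance": int(row["trial"] - last_on), "rating": int(row["rating"])})
        if row["rating"] >= 4:
            last_on = int(row["trial"])
    return pd.DataFrame(rows, columns=["distance", "rating"])


def spearman_rating_drift(data: pd.DataFrame) -> dict:
    """Per-subject Spearman rho of ON/OFF likelihood against distance from
    an ON report, tested against zero across subjects with one-sample t.

    ``data`` needs columns ``subject``, ``distance``, ``rating``.  Subjects
    with fewer than 3 distinct distances, or all-tied likelihoods (rho
    undefined), are excluded and logged.
    """
    from scipy import stats as sps

    required = {"subject", "distance", "rating"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    rho_on, rho_off, excluded = [], [], 0
    for s, sub in data.groupby("subject"):
        grouped = sub.groupby("distance")["rating"]
        dist = np.array(sorted(sub["distance"].unique()))
        if dist.size < 3:
            excluded += 1
            continue
        on_lik = grouped.apply(lambda r: np.mean(r >= 4)).loc[dist].to_numpy()
        off_lik = grouped.apply(lambda r: np.mean(r <= 2)).loc[dist].to_numpy()
        dist = dist.astype(float)
        if np.allclose(on_lik, on_lik[0]) or np.allclose(off_lik, off_lik[0]):
            excluded += 1
            continue
        rho_on.append(sps.spearmanr(dist, on_lik).statistic)
        rho_off.append(sps.spearmanr(dist, off_lik).statistic)
    if excluded:
        logger.info("spearman_rating_drift: excluded %d subject(s)", excluded)
    if len(rho_on) < 2:
        raise ValueError("fewer than 2 usable subjects")
    t_on, p_on = sps.ttest_1samp(rho_on, 0.0)
    t_off, p_off = sps.ttest_1samp(rho_off, 0.0)
    return {
        "rho_on": np.asarray(rho_on),
        "rho_off": np.asarray(rho_off),
        "t_on": TestResult(float(t_on), float(p_on), df=(len(rho_on) - 1.0,), label="rho_on_vs_0"),
        "t_off": TestResult(float(t_off), float(p_off), df=(len(rho_off) - 1.0,), label="rho_off_vs_0"),
        "n_excluded": excluded,
    }
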