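"""End-to-end pipeline: simulate → decode → dynamics → behavior → neural.

Each stage is a plain function over library objects so that analysis
scripts, tests and the acceptance script can drive any subset;
:func:`run_pipeline` chains them, writes results tables (CSV) and test
reports (JSON) to the configured output directory and returns a manifest
recording the config hash, seed and every output file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import dynamics as dyn
from . import neural as neu
from .decoding import pooled_band_decoding
from .io import PipelineConfig, _jsonable
from .preprocessing import (
    bandpass,
    bandpass_hilbert_envelope,
    baseline_correct,
    baseline_zscore,
    build_band_bank,
    extract_epochs,
    reject_artifacts,
)
from .synthetic import SyntheticSession, generate_session, rating_to_state

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "simulate_stage", "decode_stage",
           "dynamics_stage", "behavior_stage", "neural_stage", "merge_labels"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    outputs: list[str] = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0
    stage_info: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def subject_seeds(seed: int, n_subjects: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31 - 1)) for s in ss.generate_state(n_subjects)]


def simulate_stage(cfg: PipelineConfig) -> list[SyntheticSession]:
    return [
        generate_session(cfg.simulation_config(seed=s))
        for s in subject_seeds(cfg.seed, cfg.n_subjects)
    ]


def decode_stage(cfg: PipelineConfig, sessions: list[SyntheticSession]):
    fs = sessions[0].recording.sampling_rate
    bank = build_band_bank(
        cfg.decoding.f_min, cfg.decoding.f_max, cfg.decoding.n_bands, sampling_rate=fs
    )
    results, selected, predictions = pooled_band_decoding(
        sessions,
        bank,
        target_rate=cfg.decoding.target_rate,
        grid=cfg.decoding.grid,
        n_folds=cfg.decoding.n_folds,
        seed=cfg.seed,
    )
    table = pd.DataFrame(
        {
            "center_hz": [r.band[0] for r in results],
            "low_hz": [r.band[1] for r in results],
            "high_hz": [r.band[2] for r in results],
            "accuracy_5class": [r.accuracy_5class for r in results],
            "accuracy_3class": [r.accuracy_3class for r in results],
            "delta_r": [r.delta_r for r in results],
            "selected": [i == selected for i in range(len(results))],
        }
    )
    return results, selected, predictions, table


def merge_labels(
    sessions: list[SyntheticSession], predictions: pd.DataFrame
) -> list[pd.DataFrame]:
    """Per-session trial tables with reported (probed) or predicted labels.

    Adds ``rating_merged``, ``state_merged`` and ``label_type``
    (reported/predicted); trials without either label are dropped.
    """
    out = []
    for si, sess in enumerate(sessions):
        t = sess.trials.copy()
        pred = predictions[predictions["subject"] == si].set_index("trial")["rating_pred"]
        t["rating_merged"] = t["rating"]
        unprobed = ~t["probed"]
        t.loc[unprobed, "rating_merged"] = t.loc[unprobed, "trial"].map(pred)
        t = t.dropna(subset=["rating_merged"])
        t["rating_merged"] = t["rating_merged"].astype(int)
        t["state_merged"] = t["rating_merged"].map(rating_to_state)
        t["label_type"] = np.where(t["probed"], "reported", "predicted")
        out.append(t)
    return out


def dynamics_stage(
    cfg: PipelineConfig,
    sessions: list[SyntheticSession],
    predictions: pd.DataFrame,
) -> dict:
    fq_ratings, fq1_pred, all_pred, evo_rows, spear_rows = [], [], [], [], []
    for si, sess in enumerate(sessions):
        t = sess.trials
        pred = predictions[predictions["subject"] == si].set_index("trial")["rating_pred"]
        fq_ratings.append(t.loc[t["probed"], "rating"].astype(int).to_list())
        pos = t.set_index("trial")["position_from_probe"]
        fq1 = [int(pred[tr]) for tr in pred.index if pos.get(tr) == 1.0]
        fq1_pred.append(fq1)
        all_pred.append(pred.astype(int).to_list())
        for tr in pred.index:
            p = pos.get(tr)
            if p is not None and np.isfinite(p):
                evo_rows.append(
                    {"subject": si, "position": int(p), "rating": int(pred[tr])}
                )
        d = dyn.on_report_distances(t)
        d["subject"] = si
        spear_rows.append(d)

    interruption = dyn.probe_interruption_test(
        fq_ratings, fq1_pred, all_pred, n_iter=cfg.dynamics.n_iter, seed=cfg.seed
    )
    evolution = dyn.evolution_composite(
        pd.DataFrame(evo_rows),
        n_max=cfg.dynamics.n_max,
        n_iter=cfg.dynamics.n_iter,
        seed=cfg.seed + 1,
    )
    try:
        spearman = dyn.spearman_rating_drift(pd.concat(spear_rows, ignore_index=True))
    except ValueError as err:
        logger.warning("dynamics_stage: spearman variant skipped (%s)", err)
        spearman = None
    return {"interruption": interruption, "evolution": evolution, "spearman": spearman}


def _complete_crossing(cells: pd.DataFrame) -> bool:
    """True when the pivoted columns form the full factor product."""
    lvl_a = cells.columns.get_level_values(0).unique()
    lvl_b = cells.columns.get_level_values(1).unique()
    complete = len(cells.columns) == len(lvl_a) * len(lvl_b)
    if not complete:
        logger.warning("behavior_stage: incomplete design crossing; ANOVA skipped")
    return complete


def behavior_stage(
    cfg: PipelineConfig,
    sessions: list[SyntheticSession],
    predictions: pd.DataFrame,
) -> dict:
    merged = merge_labels(sessions, predictions)
    # per-subject accuracy by state and label type
    rows = []
    for si, t in enumerate(merged):
        keep = beh.rt_filter(t["rt"].to_numpy())
        t = t[keep]
        for (state, ltype), grp in t.groupby(["state_merged", "label_type"]):
            if len(grp):
                rows.append(
                    {
                        "subject": si,
                        "state": state,
                        "label_type": ltype,
                        "accuracy_pct": 100.0 * grp["correct"].mean(),
                        "rt_mean_ms": 1000.0 * grp["rt"].mean(),
                    }
                )
    acc_df = pd.DataFrame(rows)
    label_anova = None
    cells = acc_df.pivot_table(
        index="subject", columns=["state", "label_type"], values="accuracy_pct"
    ).dropna()
    if len(cells) >= 2 and _complete_crossing(cells):
        long = cells.stack(list(range(cells.columns.nlevels)), future_stack=True).rename(
            "accuracy_pct"
        ).reset_index()
        label_anova = beh.behavior_tests(
            long,
            dv="accuracy_pct",
            factor_a="state",
            factor_b="label_type",
            n_iter=cfg.stats.n_perm,
            seed=cfg.seed + 2,
        )

    # psychometric fit per merged state, pooled across subjects
    pooled = pd.concat(merged, ignore_index=True)
    pooled = pooled[beh.rt_filter(pooled["rt"].to_numpy())]
    fits = {}
    for state, grp in pooled.groupby("state_merged"):
        try:
            fit = beh.fit_psychometric(grp["tilt"].to_numpy(), grp["correct"].to_numpy())
            fits[state] = fit
        except ValueError as err:
            logger.warning("behavior_stage: psychometric fit skipped for %s (%s)", state, err)

    # state x threshold level accuracy, per subject
    lvl_rows = []
    for si, t in enumerate(merged):
        t = t[beh.rt_filter(t["rt"].to_numpy())].copy()
        t["level"] = t["tilt"].map(beh.threshold_levels)
        t = t[t["level"] != "excluded"]
        for (state, level), grp in t.groupby(["state_merged", "level"]):
            lvl_rows.append(
                {
                    "subject": si,
                    "state": state,
                    "level": level,
                    "accuracy_pct": 100.0 * grp["correct"].mean(),
                    "rt_mean_ms": 1000.0 * grp["rt"].mean(),
                    "rt_sd_ms": 1000.0 * grp["rt"].std(ddof=1),
                    "rt_cv": beh.rt_cv(grp["rt"].to_numpy()) if len(grp) > 1 else np.nan,
                }
            )
    lvl_df = pd.DataFrame(lvl_rows)
    level_anova = None
    cells = lvl_df.pivot_table(index="subject", columns=["state", "level"], values="accuracy_pct").dropna()
    if len(cells) >= 2 and _complete_crossing(cells):
        long = cells.stack(list(range(cells.columns.nlevels)), future_stack=True).rename(
            "accuracy_pct"
        ).reset_index()
        level_anova = beh.behavior_tests(
            long,
            dv="accuracy_pct",
            factor_a="state",
            factor_b="level",
            n_iter=cfg.stats.n_perm,
            seed=cfg.seed + 3,
        )
    return {
        "accuracy_by_label_type": acc_df,
        "label_anova": label_anova,
        "psychometric": fits,
        "summary_by_level": lvl_df,
        "level_anova": level_anova,
    }


def neural_stage(
    cfg: PipelineConfig,
    sessions: list[SyntheticSession],
    predictions: pd.DataFrame,
) -> dict:
    merged = merge_labels(sessions, predictions)
    ncfg = cfg.neural
    bha_series, on_series, off_series = [], [], []
    supra_means, sub_means = [], []
    c1_z, bha_z = [], []
    times = None
    for si, sess in enumerate(sessions):
        env = bandpass_hilbert_envelope(sess.recording, ncfg.band)
        epochs = extract_epochs(env, "stimulus", ncfg.window)
        epochs, _ = reject_artifacts(epochs)
        z = baseline_zscore(epochs, ncfg.baseline)
        times = z.times
        chans = neu.stimulus_responsive_channels(z, ncfg.z_thresh, ncfg.min_duration)
        if not chans:
            chans = sess.recording.channel_groups.get("occipital", z.channel_labels)
        ci = [z.channel_labels.index(c) for c in chans]
        series = z.data[:, ci, :].mean(axis=1)  # (trials, T)
        bha_series.append(series.mean(axis=0))
        bha_z.append(series.mean(axis=0))

        labels = merged[si].set_index("trial")["state_merged"]
        trial_states = z.metadata["trial"].map(labels)
        on_mask = (trial_states == "ON").to_numpy()
        off_mask = (trial_states == "OFF").to_numpy()
        if on_mask.any() and off_mask.any():
            on_series.append(series[on_mask].mean(axis=0))
            off_series.append(series[off_mask].mean(axis=0))

        levels = z.metadata["tilt"].map(beh.threshold_levels)
        m_supra = (levels == "supra").to_numpy()
        m_sub = (levels == "sub").to_numpy()
        if m_supra.any() and m_sub.any():
            supra_means.append(series[m_supra].mean(axis=0))
            sub_means.append(series[m_sub].mean(axis=0))

        # C1: ERP-band filter, baseline correct, collapse across visual fields
        erp = bandpass(sess.recording, ncfg.erp_band)
        eep = extract_epochs(erp, "stimulus", ncfg.window)
        eep = baseline_correct(eep, ncfg.baseline)
        vf = eep.metadata["visual_field"].to_numpy()
        uvf = eep.select(np.flatnonzero(vf == "UVF"))
        lvf = eep.select(np.flatnonzero(vf == "LVF"))
        if uvf.n_trials and lvf.n_trials:
            collapsed = neu.collapse_c1(uvf, lvf)
            bmask = eep.time_mask(*ncfg.baseline)
            mu, sd = collapsed[bmask].mean(), collapsed[bmask].std(ddof=1)
            c1_z.append((collapsed - mu) / sd if sd > 0 else collapsed * 0.0)

    bha_stack = np.vstack(bha_series)
    window, q = neu.response_window_circshift(
        bha_stack, times, n_iter=ncfg.n_iter, seed=cfg.seed + 4
    )
    out: dict = {"response_window": window, "times": times, "bha_mean": bha_stack.mean(axis=0)}

    if window is not None and supra_means:
        wmask = (times * 1000 >= window.onset_ms) & (times * 1000 <= window.offset_ms)
        out["orientation"] = neu.orientation_contrast(
            np.vstack(supra_means)[:, wmask].mean(axis=1),
            np.vstack(sub_means)[:, wmask].mean(axis=1),
        )
    if len(on_series) >= 2:
        on_stack, off_stack = np.vstack(on_series), np.vstack(off_series)
        out["state_contrast"] = neu.state_contrast_timecourse(
            on_stack, off_stack, times, n_perm=cfg.stats.n_perm, seed=cfg.seed + 5
        )
        out["flanks"] = neu.flank_contrast(
            on_stack, off_stack, times, n_perm=cfg.stats.n_perm, seed=cfg.seed + 6
        )
    if len(c1_z) >= 3 and len(c1_z) == len(bha_z):
        c1_stack = np.vstack(c1_z)
        try:
            lat = neu.latency_comparison(c1_stack, np.vstack(bha_z), times, ncfg.z_thresh)
            out["latency"] = lat
            peak_amps = np.array(
                [c1_stack[i, np.argmin(np.abs(times * 1000 - lat.c1_peak_ms[i]))]
                 for i in range(len(lat.c1_peak_ms))]
            )
            if peak_amps.size >= 5:
                out["c1_bha_correlation"] = neu.c1_bha_correlation(
                    peak_amps,
                    np.vstack(bha_z)[: peak_amps.size],
                    times,
                    n_iter=ncfg.n_iter,
                    seed=cfg.seed + 7,
                )
        except ValueError as err:
            logger.warning("neural_stage: latency comparison skipped (%s)", err)
    return out


def _json_report(obj) -> object:
    """Recursively convert stage outputs into JSON-serializable structures."""
    from .stats import TestResult

    if isinstance(obj, TestResult):
        return obj.to_dict()
    if isinstance(obj, beh.PsychometricFit):
        return {
            "a": obj.a, "b": obj.b, "c": obj.c, "d": obj.d,
            "converged": obj.converged, "threshold_75": obj.threshold_75,
        }
    if isinstance(obj, neu.ResponseWindow):
        return {
            "onset_ms": obj.onset_ms,
            "offset_ms": obj.offset_ms,
            "peak_time_ms": obj.peak_time_ms,
            "peak_value": obj.peak_value,
        }
    if isinstance(obj, neu.LatencyStats):
        return {
            "c1_onset_ms_mean": float(np.mean(obj.c1_onset_ms)),
            "bha_onset_ms_mean": float(np.mean(obj.bha_onset_ms)),
            "c1_peak_ms_mean": float(np.mean(obj.c1_peak_ms)),
            "bha_peak_ms_mean": float(np.mean(obj.bha_peak_ms)),
            "onset_t": obj.onset_t.to_dict(),
            "peak_t": obj.peak_t.to_dict(),
            "onset_r": obj.onset_r.to_dict(),
            "peak_r": obj.peak_r.to_dict(),
        }
    if isinstance(obj, dyn.EvolutionResult):
        return {
            "r_on": obj.r_on.to_dict(),
            "r_off": obj.r_off.to_dict(),
            "pairwise": obj.pairwise.to_dict(orient="list"),
        }
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, dict):
        return {k: _json_report(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_report(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj)
    return _jsonable(obj)


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute every stage and write results under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=cfg.config_hash(), seed=cfg.seed, started=time.time())

    sessions = simulate_stage(cfg)
    trials = pd.concat(
        [s.trials.assign(subject=si) for si, s in enumerate(sessions)], ignore_index=True
    )
    _write_csv(trials, out / "trials.csv", manifest)
    manifest.stage_info["simulate"] = {
        "n_subjects": len(sessions),
        "n_trials_per_subject": int(sessions[0].config.n_trials),
    }

    results, selected, predictions, band_table = decode_stage(cfg, sessions)
    _write_csv(band_table, out / "band_decoding.csv", manifest)
    _write_csv(predictions, out / "predictions.csv", manifest)
    manifest.stage_info["decode"] = {
        "selected_center_hz": results[selected].band[0],
        "selected_delta_r": results[selected].delta_r,
    }

    dyn_out = dynamics_stage(cfg, sessions, predictions)
    (out / "dynamics.json").write_text(json.dumps(_json_report(dyn_out), indent=1))
    manifest.outputs.append(str(out / "dynamics.json"))
    evo = dyn_out["evolution"]
    _write_csv(
        pd.DataFrame(
            {
                "position": evo.series.positions,
                "on_likelihood": np.nanmean(evo.series.on, axis=0),
                "off_likelihood": np.nanmean(evo.series.off, axis=0),
                "composite": np.nanmean(evo.composite, axis=0),
            }
        ),
        out / "evolution.csv",
        manifest,
    )

    beh_out = behavior_stage(cfg, sessions, predictions)
    _write_csv(beh_out["summary_by_level"], out / "behavior_summary.csv", manifest)
    (out / "behavior_tests.json").write_text(
        json.dumps(
            _json_report({k: v for k, v in beh_out.items() if "summary" not in k}), indent=1
        )
    )
    manifest.outputs.append(str(out / "behavior_tests.json"))

    neu_out = neural_stage(cfg, sessions, predictions)
    _write_csv(
        pd.DataFrame({"time_s": neu_out["times"], "bha_mean_z": neu_out["bha_mean"]}),
        out / "bha_timecourse.csv",
        manifest,
    )
    (out / "neural.json").write_text(
        json.dumps(
            _json_report({k: v for k, v in neu_out.items() if k not in ("times", "bha_mean")}),
            indent=1,
        )
    )
    manifest.outputs.append(str(out / "neural.json"))

    manifest.finished = time.time()
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=1))
    return manifest


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, index=False)
    manifest.outputs.append(str(path))
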