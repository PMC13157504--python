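"""Probe interruption and the evolution of the attentional state.

Tests whether thought probes interrupt mind-wandering (OFF likelihood drops
from the probed trial to the next, against a random-trial surrogate) and
how the decoded ON/OFF likelihoods evolve with trials since the probe
(correlation with position, composite measure, pairwise FQ+1 vs FQ+N tests
with FDR, plus the Spearman drift variant).
"""

import json
import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RESULTS, load_or_decode, parse_seed, study_config

from statewave.pipeline import _json_report, dynamics_stage, simulate_stage


def main() -> None:
    warnings.filterwarnings("ignore")
    seed = parse_seed(__doc__)
    cfg = study_config(seed)
    sessions = simulate_stage(cfg)
    predictions = load_or_decode(cfg, sessions)

    out = dynamics_stage(cfg, sessions, predictions)
    RESULTS.mkdir(parents=True, exist_ok=True)
    (RESULTS / "dynamics.json").write_text(json.dumps(_json_report(out), indent=1))

    evo = out["evolution"]
    pd.DataFrame(
        {
            "position": evo.series.positions,
            "on_likelihood": np.nanmean(evo.series.on, axis=0),
            "off_likelihood": np.nanmean(evo.series.off, axis=0),
            "composite": np.nanmean(evo.composite, axis=0),
        }
    ).to_csv(RESULTS / "evolution.csv", index=False)

    inter = out["interruption"]
    print(f"probe interruption: trial-type F = {inter['f_trial_type'].statistic:.1f} "
          f"(surrogate p = {inter['f_trial_type'].p:.4f}), "
          f"interaction p = {inter['f_interaction'].p:.4f}")
    print(f"state evolution: r_ON = {evo.r_on.statistic:.2f} (p = {evo.r_on.p:.4f}), "
          f"r_OFF = {evo.r_off.statistic:.2f} (p = {evo.r_off.p:.4f})")
    sig = evo.pairwise[evo.pairwise["q"] < 0.05]
    print(f"pairwise FQ+1 vs FQ+N: {len(sig)}/{len(evo.pairwise)} positions with q < 0.05")
    if out["spearman"] is not None:
        sp = out["spearman"]
        print(f"spearman drift: mean rho_ON = {sp['rho_on'].mean():.2f} "
              f"(t = {sp['t_on'].statistic:.2f}, p = {sp['t_on'].p:.4f}); "
              f"mean rho_OFF = {sp['rho_off'].mean():.2f} "
              f"(t = {sp['t_off'].statistic:.2f}, p = {sp['t_off'].p:.4f})")
    print(f"wrote {RESULTS/'dynamics.json'} and {RESULTS/'evolution.csv'}")


if __name__ == "__main__":
    main()
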