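"""Simulate the synthetic cohort and summarize its structure.

Generates one session per subject (latent attentional state drifting from
ON toward OFF between thought probes, state-dependent theta power, evoked
high-frequency bursts, C1 deflections, behavior) and writes the pooled
trial table plus a per-subject summary.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RESULTS, parse_seed, study_config

from statewave.pipeline import simulate_stage


def main() -> None:
    seed = parse_seed(__doc__)
    cfg = study_config(seed)
    sessions = simulate_stage(cfg)
    RESULTS.mkdir(parents=True, exist_ok=True)

    trials = pd.concat(
        [s.trials.assign(subject=i) for i, s in enumerate(sessions)], ignore_index=True
    )
    trials.to_csv(RESULTS / "trials.csv", index=False)

    rows = []
    for i, s in enumerate(sessions):
        t = s.trials
        probed = t[t["probed"]]
        rows.append(
            {
                "subject": i,
                "n_trials": len(t),
                "n_probes": len(probed),
                "off_likelihood": (probed["rating"] <= 2).mean(),
                "on_likelihood": (probed["rating"] >= 4).mean(),
                "accuracy_pct": 100 * t["correct"].mean(),
                "rt_mean_ms": 1000 * t["rt"].mean(),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False)

    print(f"simulated {len(sessions)} subjects x {len(sessions[0].trials)} trials (seed {seed})")
    print(summary.round(3).to_string(index=False))
    print(f"wrote {RESULTS/'trials.csv'} and {RESULTS/'cohort_summary.csv'}")


if __name__ == "__main__":
    main()
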