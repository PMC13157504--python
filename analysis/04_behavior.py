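"""Behavioral performance as a function of attentional state.

Compares accuracy between reported and decoded labels, fits state-wise
psychometric functions (75% threshold), and summarizes reaction-time mean,
spread and coefficient of variation by state and threshold level.
"""

import json
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RESULTS, load_or_decode, parse_seed, study_config

from statewave.pipeline import _json_report, behavior_stage, simulate_stage


def main() -> None:
    warnings.filterwarnings("ignore")
    seed = parse_seed(__doc__)
    cfg = study_config(seed)
    sessions = simulate_stage(cfg)
    predictions = load_or_decode(cfg, sessions)

    out = behavior_stage(cfg, sessions, predictions)
    RESULTS.mkdir(parents=True, exist_ok=True)
    out["summary_by_level"].to_csv(RESULTS / "behavior_summary.csv", index=False)
    (RESULTS / "behavior_tests.json").write_text(
        json.dumps(_json_report({k: v for k, v in out.items() if "summary" not in k}), indent=1)
    )

    for state, fit in sorted(out["psychometric"].items()):
        print(f"{state}: threshold_75 = {fit.threshold_75:.2f} deg "
              f"(a={fit.a:.2f}, b={fit.b:.2f})")
    pivot = (
        out["summary_by_level"]
        .groupby(["state", "level"])[["accuracy_pct", "rt_mean_ms", "rt_cv"]]
        .mean()
        .round(1)
    )
    print(pivot.to_string())
    if out["level_anova"] is not None:
        a = out["level_anova"]["A"]
        print(f"state effect on accuracy: F = {a['parametric'].statistic:.2f}, "
              f"surrogate p = {a['surrogate_p']:.4f}")
    print(f"wrote {RESULTS/'behavior_summary.csv'} and {RESULTS/'behavior_tests.json'}")


if __name__ == "__main__":
    main()
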