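"""Broadband high-frequency activity (BHA): stimulus response and contrasts.

Extracts the 80–150 Hz Hilbert envelope, selects stimulus-responsive
channels (z > 3 for >= 100 ms), determines the significant response window
against a circular-shift surrogate, and contrasts the window-averaged
envelope between supra- and sub-threshold tilts and between ON and OFF
states (time-resolved and per burst flank).
"""

import json
import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RESULTS, load_or_decode, parse_seed, study_config

from statewave.pipeline import _json_report, neural_stage, simulate_stage


def main() -> None:
    warnings.filterwarnings("ignore")
    seed = parse_seed(__doc__)
    cfg = study_config(seed)
    sessions = simulate_stage(cfg)
    predictions = load_or_decode(cfg, sessions)

    out = neural_stage(cfg, sessions, predictions)
    RESULTS.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": out["times"], "bha_mean_z": out["bha_mean"]}).to_csv(
        RESULTS / "bha_timecourse.csv", index=False
    )
    (RESULTS / "bha_response.json").write_text(
        json.dumps(
            _json_report(
                {k: v for k, v in out.items() if k not in ("times", "bha_mean", "latency",
                                                           "c1_bha_correlation")}
            ),
            indent=1,
        )
    )

    w = out["response_window"]
    if w is not None:
        print(f"BHA response window: {w.onset_ms:.0f}-{w.offset_ms:.0f} ms, "
              f"peak z = {w.peak_value:.2f} at {w.peak_time_ms:.0f} ms")
    if "orientation" in out:
        o = out["orientation"]
        print(f"supra vs sub tilt: t = {o.statistic:.2f}, p = {o.p:.4f} (directed)")
    if "state_contrast" in out:
        print(f"ON vs OFF significant interval(s): {out['state_contrast']['intervals_ms']}")
    if "flanks" in out:
        f = out["flanks"]
        print(f"rising flank ON>OFF: t = {f['rising'].statistic:.2f}, p = {f['rising'].p:.4f}; "
              f"falling flank: t = {f['falling'].statistic:.2f}, p = {f['falling'].p:.4f}")
    print(f"wrote {RESULTS/'bha_timecourse.csv'} and {RESULTS/'bha_response.json'}")


if __name__ == "__main__":
    main()
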