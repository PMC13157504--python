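"""Shared study configuration for the numbered analysis scripts.

One place defines the synthetic cohort (the study conditions) and the
statistical settings, so every script analyses the same simulated study.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from statewave.io import PipelineConfig

RESULTS = Path(__file__).resolve().parents[1] / "results" / "analysis"


def study_config(seed: int) -> PipelineConfig:
    return PipelineConfig(
        seed=seed,
        out_dir=str(RESULTS),
        n_subjects=10,
        simulation={
            "n_trials": 220,
            "trial_duration": 1.91,
            "pre_stim": 0.5,
            "n_channels": 4,
            "probe_fraction": 0.25,
        },
        decoding={
            "f_min": 3.0,
            "f_max": 180.0,
            "n_bands": 27,
            "grid": {"C": [1], "kernel": ["rbf"]},
        },
        dynamics={"n_iter": 500, "n_max": 25},
        neural={"n_iter": 500},
        stats={"n_perm": 500},
    )


def parse_seed(description: str) -> int:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    return parser.parse_args().seed


def load_or_decode(cfg: PipelineConfig, sessions):
    """Reuse the prediction table written by 02_band_decoding.py when
    available; otherwise run the decoding stage now."""
    import pandas as pd

    from statewave.pipeline import decode_stage

    path = RESULTS / "predictions.csv"
    if path.exists():
        return pd.read_csv(path)
    _, _, predictions, _ = decode_stage(cfg, sessions)
    return predictions
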