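"""Session serialization and pipeline configuration.

A session is stored as a directory: the recording as a binary array
container (``recording.npy``) with a JSON sidecar carrying the sampling
rate, channel labels/groups, events and generator config; the trial table
as CSV; the latent truth as CSV.  Round trips are lossless (arrays
bit-exact, metadata field-exact).  Epochs can optionally be exported to
the FIF epochs format for interoperability with standard M/EEG tooling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .preprocessing import Epochs, Event, Recording
from .synthetic import LatentStateTrajectory, SimulationConfig, SyntheticSession

__all__ = [
    "PipelineConfig",
    "load_config",
    "write_session",
    "read_session",
    "export_epochs_fif",
    "import_epochs_fif",
]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_session(session: SyntheticSession, path: str | Path) -> Path:
    """Write a session to ``path`` (a directory, created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "recording.npy", session.recording.data)
    sidecar = {
        "sampling_rate": session.recording.sampling_rate,
        "channel_labels": session.recording.channel_labels,
        "channel_groups": session.recording.channel_groups,
        "events": [
            {"time": ev.time, "kind": ev.kind, "payload": _jsonable(ev.payload)}
            for ev in session.recording.events
        ],
        "config": _jsonable(dataclasses.asdict(session.config)),
    }
    (path / "recording.json").write_text(json.dumps(sidecar, indent=1))
    session.trials.to_csv(path / "trials.csv", index=False)
    pd.DataFrame({"rating": session.truth.ratings}).to_csv(path / "truth.csv", index=False)
    return path


def _restore_config(raw: dict) -> SimulationConfig:
    cfg = dict(raw)
    for key in ("bha_band", "bha_window", "bha_state_gain_window"):
        if cfg.get(key) is not None:
            cfg[key] = tuple(cfg[key])
    for key in ("psychometric_params", "rt_params"):
        if key in cfg:
            cfg[key] = {k: tuple(v) for k, v in cfg[key].items()}
    return SimulationConfig(**cfg)


def read_session(path: str | Path) -> SyntheticSession:
    """Read a session written by :func:`write_session`."""
    path = Path(path)
    for fname in ("recording.npy", "recording.json", "trials.csv", "truth.csv"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"session file missing: {path / fname}")
    try:
        data = np.load(path / "recording.npy")
    except (ValueError, EOFError) as err:
        raise ValueError(f"corrupt array container {path / 'recording.npy'}: {err}") from err
    try:
        sidecar = json.loads((path / "recording.json").read_text())
    except json.JSONDecodeError as err:
        raise ValueError(
            f"corrupt sidecar {path / 'recording.json'} at offset {err.pos}: {err.msg}"
        ) from err
    events = [
        Event(time=ev["time"], kind=ev["kind"], payload=ev.get("payload", {}))
        for ev in sidecar["events"]
    ]
    rec = Recording(
        data=data,
        sampling_rate=sidecar["sampling_rate"],
        channel_labels=list(sidecar["channel_labels"]),
        events=events,
        channel_groups={k: list(v) for k, v in sidecar["channel_groups"].items()},
    )
    trials = pd.read_csv(path / "trials.csv")
    truth = LatentStateTrajectory(
        ratings=pd.read_csv(path / "truth.csv")["rating"].to_numpy()
    )
    return SyntheticSession(
        recording=rec, trials=trials, truth=truth, config=_restore_config(sidecar["config"])
    )


def export_epochs_fif(epochs: Epochs, path: str | Path) -> Path:
    """Export epochs to the FIF epochs format (float32 on disk)."""
    import mne

    path = Path(path)
    info = mne.create_info(
        ch_names=list(epochs.channel_labels), sfreq=epochs.sampling_rate, ch_types="misc"
    )
    arr = mne.EpochsArray(epochs.data, info, tmin=epochs.window[0], verbose="error")
    arr.save(path, overwrite=True, verbose="error")
    return path


def import_epochs_fif(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read back FIF epochs: (data, sampling_rate, channel_labels)."""
    import mne

    ep = mne.read_epochs(Path(path), preload=True, verbose="error")
    return ep.get_data(), float(ep.info["sfreq"]), list(ep.ch_names)


# ---------------------------------------------------------------------------
# Pipeline configuration


class DecodingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    f_min: float = 3.0
    f_max: float = 180.0
    n_bands: int = 27
    grid: dict = Field(default_factory=lambda: {"C": [1], "kernel": ["rbf"]})
    n_folds: int = 5
    target_rate: float | None = None

    @field_validator("n_folds")
    @classmethod
    def _folds(cls, v):
        if v < 2:
            raise ValueError("n_folds must be >= 2")
        return v


class DynamicsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_max: int = 25
    n_iter: int = 1000

    @field_validator("n_iter")
    @classmethod
    def _iters(cls, v):
        if v < 100:
            raise ValueError("n_iter must be >= 100")
        return v


class NeuralSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    band: tuple[float, float] = (80.0, 150.0)
    erp_band: tuple[float, float] = (1.0, 40.0)
    window: tuple[float, float] = (-0.3, 0.7)
    baseline: tuple[float, float] = (-0.2, 0.0)
    z_thresh: float = 3.0
    min_duration: float = 0.1
    n_iter: int = 1000

    @field_validator("n_iter")
    @classmethod
    def _iters(cls, v):
        if v < 100:
            raise ValueError("n_iter must be >= 100")
        return v


class StatsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_perm: int = 1000
    alpha: float = 0.05

    @field_validator("n_perm")
    @classmethod
    def _perms(cls, v):
        if v < 100:
            raise ValueError("n_perm must be >= 100")
        return v


class PipelineConfig(BaseModel):
    """Validated end-to-end pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "results/pipeline"
    n_subjects: int = 6
    simulation: dict = Field(default_factory=dict)  # SimulationConfig overrides
    decoding: DecodingSection = Field(default_factory=DecodingSection)
    dynamics: DynamicsSection = Field(default_factory=DynamicsSection)
    neural: NeuralSection = Field(default_factory=NeuralSection)
    stats: StatsSection = Field(default_factory=StatsSection)

    @field_validator("n_subjects")
    @classmethod
    def _subs(cls, v):
        if v < 2:
            raise ValueError("n_subjects must be >= 2")
        return v

    @field_validator("simulation")
    @classmethod
    def _sim(cls, v):
        SimulationConfig(**{**v, "seed": 0})  # raises on invalid keys/values
        return v

    def simulation_config(self, seed: int | None = None) -> SimulationConfig:
        overrides = dict(self.simulation)
        overrides["seed"] = self.seed if seed is None else seed
        return _restore_config(overrides)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**raw)
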