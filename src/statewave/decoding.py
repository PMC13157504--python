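"""Per-band single-trial brain-state classification.

Features are the band-passed epoch time series of all channels concatenated
into one vector per trial (after integer-factor decimation), z-normalized
per column on training rows only.  The classifier is a one-vs-one SVM with
a small hyperparameter grid, stratified cross-validation and optional data
augmentation (noise copies, window shifts, phase-shifted subsampling).  The
band whose predicted rating distribution deviates least from the reported
distribution (the Δ_R criterion, root of the summed squared differences) is
selected for downstream analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedGroupKFold,
    StratifiedKFold,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocessing import (
    BandBank,
    Epochs,
    bandpass,
    bandpass_hilbert_envelope,
    extract_epochs,
)
from .synthetic import SyntheticSession, rating_to_state

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "AugmentationSpec",
    "DecodingResult",
    "assemble_features",
    "augment",
    "train_state_classifier",
    "delta_R",
    "select_band",
    "rbf_gamma",
    "run_band_decoding",
    "DEFAULT_GRID",
]

DEFAULT_GRID = {"C": [0.01, 0.05, 0.1, 1, 10], "kernel": ["linear", "rbf", "sigmoid"]}

RATING_LEVELS = np.array([1, 2, 3, 4, 5])


def rbf_gamma(n_features: int, sigma_data: float) -> float:
    """RBF kernel width ``gamma = 1 / (N_features * sigma_data)``."""
    if n_features <= 0 or sigma_data <= 0:
        raise ValueError("n_features and sigma_data must be positive")
    return 1.0 / (n_features * sigma_data)


@dataclass
class FeatureMatrix:
    """Trials × (channels × time) features with provenance accounting."""

    X: np.ndarray  # (n_trials, n_features)
    n_channels: int
    n_samples: int  # per channel, after decimation
    decimation_factor: int
    original_rate: float
    raw: np.ndarray | None = None  # pre-decimation epochs, for phase upsampling
    dropped_columns: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def acquisition_throughput(self) -> float:
        """Data points per second of acquisition: channels × sampling rate."""
        return self.n_channels * self.original_rate

    @property
    def reduction_factor(self) -> int:
        """Feature-space reduction achieved by the downsampling step."""
        return self.decimation_factor


def assemble_features(
    epochs: Epochs, target_rate: float = 500.0, drop_constant: bool = True
) -> FeatureMatrix:
    """Decimate to ``target_rate`` (integer factor, stride subsampling) and
    concatenate all channels' samples into one feature vector per trial.

    Constant (zero-variance) columns are flagged and dropped before any
    normalization.  Column normalization itself is fitted on training rows
    only, inside the classifier pipeline.
    """
    factor_f = epochs.sampling_rate / target_rate
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"sampling rate {epochs.sampling_rate} is not an integer multiple "
            f"of the target rate {target_rate}"
        )
    dec = epochs.data[:, :, ::factor]
    X = dec.reshape(epochs.n_trials, -1)
    if epochs.n_trials > 1 and drop_constant:
        var = X.var(axis=0)
        dropped = var == 0.0
        if dropped.any():
            logger.info("assemble_features: dropped %d constant column(s)", int(dropped.sum()))
            X = X[:, ~dropped]
    else:
        dropped = np.zeros(X.shape[1], dtype=bool)
    return FeatureMatrix(
        X=X,
        n_channels=epochs.n_channels,
        n_samples=dec.shape[2],
        decimation_factor=factor,
        original_rate=epochs.sampling_rate,
        raw=epochs.data,
        dropped_columns=dropped,
    )


@dataclass
class AugmentationSpec:
    """Training-fold augmentation: noise copies, window shifts, phase
    upsampling (``upsample_factor - 1`` extra phase-shifted copies drawn
    from the pre-decimation series)."""

    gaussian_noise_sd: float = 0.0
    n_noise_copies: int = 0
    n_window_shifts: int = 0
    shift_step: int = 1
    upsample_factor: int = 1

    def __post_init__(self) -> None:
        if min(self.n_noise_copies, self.n_window_shifts, self.upsample_factor - 1) < 0:
            raise ValueError("augmentation counts must be >= 0")
        if self.gaussian_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    @property
    def copies_per_trial(self) -> int:
        return 1 + self.n_noise_copies + self.n_window_shifts + (self.upsample_factor - 1)


def _shift_features(X: np.ndarray, n_channels: int, n_samples: int, k: int) -> np.ndarray:
    """Shift each channel's time series by k samples with edge replication."""
    T = X.reshape(X.shape[0], n_channels, n_samples)
    out = np.empty_like(T)
    if k > 0:
        out[:, :, k:] = T[:, :, :-k]
        out[:, :, :k] = T[:, :, :1]
    elif k < 0:
        out[:, :, :k] = T[:, :, -k:]
        out[:, :, k:] = T[:, :, -1:]
    else:
        out[:] = T
    return out.reshape(X.shape[0], -1)


def augment(
    features: FeatureMatrix,
    labels: np.ndarray,
    spec: AugmentationSpec,
    seed: int | None = None,
    train_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Augment training rows; returns ``(X_aug, y_aug, groups)``.

    ``groups`` maps every augmented row back to its source trial so that
    cross-validation can keep all copies of one trial in the same fold
    (no leakage).  Requesting augmentation on rows outside
    ``train_indices`` is an error by construction: only the rows passed in
    are augmented, and the caller passes training rows only.
    """
    if features.dropped_columns is not None and features.dropped_columns.any():
        raise ValueError("augment before dropping columns is unsupported; re-assemble")
    idx = np.arange(features.n_trials) if train_indices is None else np.asarray(train_indices)
    if np.unique(idx).size != idx.size:
        raise ValueError("duplicate training rows")
    X = features.X[idx]
    y = np.asarray(labels)[idx]
    rng = np.random.default_rng(seed)
    blocks = [X]
    yblocks = [y]
    gblocks = [idx]

    for _ in range(spec.n_noise_copies):
        blocks.append(X + rng.normal(0.0, spec.gaussian_noise_sd, size=X.shape))
        yblocks.append(y)
        gblocks.append(idx)

    if spec.n_window_shifts:
        shifts = []
        k = 1
        while len(shifts) < spec.n_window_shifts:
            shifts.extend(s for s in (-k * spec.shift_step, k * spec.shift_step))
            k += 1
        for s in shifts[: spec.n_window_shifts]:
            blocks.append(_shift_features(X, features.n_channels, features.n_samples, s))
            yblocks.append(y)
            gblocks.append(idx)

    if spec.upsample_factor > 1:
        if features.raw is None:
            raise ValueError("phase upsampling needs the pre-decimation epochs")
        f = features.decimation_factor
        if spec.upsample_factor > f:
            raise ValueError("upsample_factor cannot exceed the decimation factor")
        for j in range(1, spec.upsample_factor):
            phased = features.raw[idx][:, :, j::f][:, :, : features.n_samples]
            blocks.append(phased.reshape(len(idx), -1))
            yblocks.append(y)
            gblocks.append(idx)

    return np.vstack(blocks), np.concatenate(yblocks), np.concatenate(gblocks)


@dataclass
class DecodingResult:
    """Per-band decoding outcome."""

    band: tuple[float, float, float] | None
    accuracy_5class: float
    accuracy_3class: float
    confusion: np.ndarray  # rows = true rating, cols = predicted rating (5x5)
    predicted_ratings: np.ndarray  # for the unlabeled trials passed in
    class_likelihoods: np.ndarray | None  # (n_unlabeled, 5) one-vs-one vote shares
    best_params: dict = field(default_factory=dict)
    delta_r: float | None = None

    @property
    def predicted_states(self) -> np.ndarray:
        return np.array([rating_to_state(int(r)) for r in self.predicted_ratings])


def _vote_shares(clf, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """One-vs-one vote shares per rating level (columns ordered 1..5)."""
    dec = clf.decision_function(X)
    k = len(classes)
    if k == 2:
        dec = dec.reshape(-1, 1)
    votes = np.zeros((X.shape[0], k))
    col = 0
    for i in range(k):
        for j in range(i + 1, k):
            win_i = dec[:, col] > 0
            votes[win_i, i] += 1
            votes[~win_i, j] += 1
            col += 1
    shares = votes / (k * (k - 1) / 2)
    out = np.zeros((X.shape[0], len(RATING_LEVELS)))
    for ci, c in enumerate(classes):
        out[:, int(c) - 1] = shares[:, ci]
    return out


def train_state_classifier(
    features: FeatureMatrix,
    ratings: Sequence[int],
    labeled_indices: np.ndarray,
    n_folds: int = 5,
    grid: dict | None = None,
    seed: int | None = None,
    augmentation: AugmentationSpec | None = None,
    test_fraction: float = 0.2,
    band: tuple[float, float, float] | None = None,
    class_weight: str | dict | None = None,
) -> DecodingResult:
    """Grid-searched one-vs-one SVM over rating levels 1–5.

    Labeled trials are split 80:20 (stratified); the best grid point is
    chosen by stratified ``n_folds``-fold cross-validated accuracy on the
    training portion (augmented copies, if any, are grouped with their
    source trial so they never straddle folds); accuracy is reported on the
    held-out 20% and the final model predicts all unlabeled trials.
    Normalization is fitted inside each training fold (no leakage).

    ``class_weight`` defaults to natural priors: re-weighting flattens the
    predicted-label marginal of a signal-free band, which would let it mimic
    the reported rating distribution and corrupt Δ_R band selection.
    """
    y_all = np.asarray(ratings)
    lab_orig = np.asarray(labeled_indices)
    lab = lab_orig
    y = y_all[lab].astype(int)
    classes, counts = np.unique(y, return_counts=True)
    rare = classes[counts < 2]
    if rare.size:
        # singleton classes cannot be stratified across the split and folds
        logger.info(
            "train_state_classifier: dropping %d labeled trial(s) of rare class(es) %s",
            int(counts[counts < 2].sum()),
            rare.tolist(),
        )
        keep = ~np.isin(y, rare)
        lab, y = lab[keep], y[keep]
        classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(
            "stratification error: need >= 2 rating classes with >= 2 labeled trials"
        )
    grid = DEFAULT_GRID if grid is None else grid
    rng = np.random.default_rng(seed)
    rs = int(rng.integers(0, 2**31 - 1))

    tr_idx, te_idx = train_test_split(
        np.arange(lab.size), test_size=test_fraction, stratify=y, random_state=rs
    )
    if augmentation is not None and augmentation.copies_per_trial > 1:
        X_tr, y_tr, groups = augment(
            features, y_all, augmentation, seed=rs, train_indices=lab[tr_idx]
        )
        cv = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=rs)
        fit_kwargs = {"groups": groups}
    else:
        X_tr, y_tr, groups = features.X[lab[tr_idx]], y[tr_idx], None
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
        fit_kwargs = {}

    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(class_weight=class_weight, gamma="scale", decision_function_shape="ovo")),
        ]
    )
    param_grid = {f"svm__{k}": v for k, v in grid.items()}
    search = GridSearchCV(pipe, param_grid, cv=cv, scoring="accuracy", n_jobs=1)
    search.fit(X_tr, y_tr, **fit_kwargs)
    model = search.best_estimator_

    X_te, y_te = features.X[lab[te_idx]], y[te_idx]
    pred_te = model.predict(X_te)
    acc5 = float(np.mean(pred_te == y_te))
    acc3 = float(
        np.mean(
            [rating_to_state(int(a)) == rating_to_state(int(b)) for a, b in zip(pred_te, y_te)]
        )
    )
    conf = np.zeros((5, 5))
    for t, p in zip(y_te, pred_te):
        conf[int(t) - 1, int(p) - 1] += 1

    unl = np.setdiff1d(np.arange(features.n_trials), lab_orig)
    if unl.size:
        pred_unl = model.predict(features.X[unl])
        shares = _vote_shares(model, features.X[unl], classes)
    else:
        pred_unl = np.array([], dtype=int)
        shares = None
    best = {k.removeprefix("svm__"): v for k, v in search.best_params_.items()}
    return DecodingResult(
        band=band,
        accuracy_5class=acc5,
        accuracy_3class=acc3,
        confusion=conf,
        predicted_ratings=pred_unl.astype(int),
        class_likelihoods=shares,
        best_params=best,
    )


def delta_R(predicted_dist: Sequence[float], reported_dist: Sequence[float]) -> float:
    """Δ_R = sqrt(sum((R_PL - R_FQ)^2)) over the 5 rating proportions."""
    p = np.asarray(predicted_dist, dtype=float)
    r = np.asarray(reported_dist, dtype=float)
    if p.shape != r.shape:
        raise ValueError("distributions must have equal length")
    for v, name in ((p, "predicted"), (r, "reported")):
        if abs(v.sum() - 1.0) > 1e-9 or np.any(v < 0):
            raise ValueError(f"{name} distribution must be non-negative and sum to 1")
    return float(np.sqrt(np.sum((p - r) ** 2)))


def rating_distribution(ratings: Sequence[int]) -> np.ndarray:
    """Proportion of each rating level 1..5."""
    r = np.asarray(ratings, dtype=int)
    if r.size == 0:
        raise ValueError("empty rating list")
    counts = np.array([(r == lev).sum() for lev in RATING_LEVELS], dtype=float)
    return counts / counts.sum()


def delta_r_standard_error(
    reported_dist: Sequence[float], n_reported: int, n_predicted: int
) -> float:
    """Sampling-noise scale of Δ_R from finite probe and prediction counts.

    Both distributions entering Δ_R are multinomial proportions; the
    per-category difference has variance ``p(1-p)(1/n_FQ + 1/n_PL)``, and
    the root of the summed variances is the scale below which two bands'
    Δ_R values are statistically indistinguishable.
    """
    p = np.asarray(reported_dist, dtype=float)
    if n_reported < 1 or n_predicted < 1:
        raise ValueError("counts must be positive")
    return float(np.sqrt(np.sum(p * (1 - p)) * (1.0 / n_reported + 1.0 / n_predicted)))


def select_band(
    per_band_results: Sequence[DecodingResult],
    reported_dist: Sequence[float],
    tol: float = 0.0,
) -> int:
    """Index of the band minimizing Δ_R.

    Bands whose Δ_R lies within ``tol`` of the minimum count as tied (with
    finite probe counts several bands typically reach the Δ_R floor); ties
    are broken by higher decoding accuracy, then lower center frequency,
    and logged.  ``tol=0`` reduces to exact ties.
    """
    if not per_band_results:
        raise ValueError("need at least one band result")
    for i, res in enumerate(per_band_results):
        if res.delta_r is None:
            res.delta_r = delta_R(rating_distribution(res.predicted_ratings), reported_dist)
    best_dr = min(res.delta_r for res in per_band_results)
    candidates = [i for i, res in enumerate(per_band_results) if res.delta_r <= best_dr + tol]
    if len(candidates) > 1:
        logger.info(
            "select_band: %d band(s) within %.4f of the Δ_R minimum; "
            "tie broken by accuracy/center frequency",
            len(candidates),
            tol,
        )
    keys = []
    for i in candidates:
        res = per_band_results[i]
        center = res.band[0] if res.band is not None else float(i)
        keys.append((-res.accuracy_5class, center, i))
    return min(keys)[2]


def pooled_band_decoding(
    sessions: Sequence[SyntheticSession],
    band_bank: BandBank,
    window: tuple[float, float] = (-0.3, 0.7),
    target_rate: float | None = None,
    grid: dict | None = None,
    n_folds: int = 5,
    seed: int | None = None,
    augmentation: AugmentationSpec | None = None,
    feature_kind: str = "envelope",
    class_weight: str | dict | None = None,
) -> tuple[list[DecodingResult], int, "pd.DataFrame"]:
    """Multi-participant band decoding with Δ_R band selection.

    For each band: band-pass every session, epoch, assemble features,
    pool trials across subjects and train one classifier on the probed
    (reported-label) trials.  The reported rating distribution pools the
    probed trials of all subjects; the predicted distribution comes from
    the unlabeled trials.  Returns the per-band results, the index of the
    Δ_R-selected band, and a trial-level prediction table for that band
    (columns subject, trial, rating_pred).

    ``feature_kind='envelope'`` (default) decodes each band's Hilbert
    amplitude-envelope time series — band amplitude carries the state
    information and envelopes are invariant to oscillation phase, which
    stabilizes decoding at modest trial counts; ``'filtered'`` uses the raw
    band-passed series instead.
    """
    import pandas as pd

    probed_blocks, rating_blocks, sub_blocks, trial_blocks = [], [], [], []
    for si, sess in enumerate(sessions):
        t = sess.trials
        probed_blocks.append(t["probed"].to_numpy(dtype=bool))
        rating_blocks.append(t["rating_true"].to_numpy())
        sub_blocks.append(np.full(len(t), si))
        trial_blocks.append(t["trial"].to_numpy())
    probed = np.concatenate(probed_blocks)
    ratings = np.concatenate(rating_blocks)
    subjects = np.concatenate(sub_blocks)
    trial_ids = np.concatenate(trial_blocks)
    reported = rating_distribution(ratings[probed])

    if feature_kind not in ("envelope", "filtered"):
        raise ValueError("feature_kind must be 'envelope' or 'filtered'")
    transform = bandpass_hilbert_envelope if feature_kind == "envelope" else bandpass
    results: list[DecodingResult] = []
    for bi, (center, lo, hi) in enumerate(band_bank):
        X_parts, raw_parts = [], []
        meta = None
        for sess in sessions:
            filtered = transform(sess.recording, (lo, hi))
            epochs = extract_epochs(filtered, "stimulus", window)
            f = assemble_features(
                epochs,
                target_rate=epochs.sampling_rate if target_rate is None else target_rate,
                drop_constant=False,
            )
            X_parts.append(f.X)
            raw_parts.append(f.raw)
            meta = f
        feats = FeatureMatrix(
            X=np.vstack(X_parts),
            n_channels=meta.n_channels,
            n_samples=meta.n_samples,
            decimation_factor=meta.decimation_factor,
            original_rate=meta.original_rate,
            raw=np.concatenate(raw_parts, axis=0),
        )
        res = train_state_classifier(
            feats,
            ratings,
            labeled_indices=np.flatnonzero(probed),
            n_folds=n_folds,
            grid=grid,
            seed=None if seed is None else seed + bi,
            augmentation=augmentation,
            band=(center, lo, hi),
            class_weight=class_weight,
        )
        res.delta_r = delta_R(rating_distribution(res.predicted_ratings), reported)
        results.append(res)

    n_fq = int(probed.sum())
    tol = delta_r_standard_error(reported, n_fq, probed.size - n_fq)
    selected = select_band(results, reported, tol=tol)
    unl = np.setdiff1d(np.arange(probed.size), np.flatnonzero(probed))
    predictions = pd.DataFrame(
        {
            "subject": subjects[unl],
            "trial": trial_ids[unl],
            "rating_pred": results[selected].predicted_ratings,
        }
    )
    return results, selected, predictions


def run_band_decoding(
    session: SyntheticSession,
    band_bank: BandBank,
    **kwargs,
) -> tuple[list[DecodingResult], int]:
    """Single-session variant of :func:`pooled_band_decoding`."""
    results, selected, _ = pooled_band_decoding([session], band_bank, **kwargs)
    return results, selected
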