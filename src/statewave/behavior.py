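"""Behavioral analyses: psychometric fitting, threshold extraction,
reaction-time statistics, and state-wise ANOVAs.

Accuracy over tilt angle x is modelled by the four-parameter logistic

    f(x) = a + (b - a) / (1 + exp(-(c x + d)))

fitted by least squares to the mean accuracy per unsigned angle.  The
perceptual threshold is the angle at which f crosses 75% correct.  Tilt
angles 1.5–4.5 deg count as sub-threshold and 7.5–15 deg as
supra-threshold; the 6 deg step belongs to neither group and is excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .stats import TestResult, anova_f, fdr_bh, surrogate_p
from .synthetic import PARADIGM_ANGLES

logger = logging.getLogger(__name__)

__all__ = [
    "PsychometricFit",
    "logistic",
    "fit_psychometric",
    "threshold_levels",
    "rt_cv",
    "rt_filter",
    "behavior_tests",
    "state_summary",
]


def logistic(x, a, b, c, d):
    """f(x) = a + (b - a) / (1 + exp(-(c x + d)))."""
    return a + (b - a) / (1.0 + np.exp(-(c * np.asarray(x, dtype=float) + d)))


@dataclass
class PsychometricFit:
    a: float
    b: float
    c: float
    d: float
    converged: bool
    residual_ss: float

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    @property
    def threshold_75(self) -> float:
        """Angle at which the fitted curve crosses 75% correct.

        Finite only when 0.75 lies strictly between the asymptotes a and b
        (and the fit converged); otherwise NaN.
        """
        if not self.converged or not (self.a < 0.75 < self.b):
            return math.nan
        return (-math.log((self.b - 0.75) / (0.75 - self.a)) - self.d) / self.c

    def predict(self, x):
        return logistic(x, *self.params)


def fit_psychometric(
    angles: Sequence[float],
    correct: Sequence[bool],
    init: Sequence[float] = (0.5, 1.0, 1.0, -6.0),
    tol: float = 1e-10,
    max_nfev: int = 20000,
) -> PsychometricFit:
    """Least-squares logistic fit to the mean accuracy per unsigned angle.

    Accuracy depends on |angle| only; at least 4 distinct unsigned angles
    and both outcomes are required.  Non-convergence yields a flagged fit
    with an undefined threshold.
    """
    x = np.abs(np.asarray(angles, dtype=float))
    y = np.asarray(correct, dtype=float)
    if x.shape != y.shape:
        raise ValueError("angles and correct must have equal length")
    uniq = np.unique(x)
    if uniq.size < 4:
        raise ValueError("need >= 4 distinct unsigned angles")
    if len(np.unique(y)) < 2:
        raise ValueError("need both correct and incorrect outcomes")
    acc = np.array([y[x == u].mean() for u in uniq])
    try:
        popt, _ = curve_fit(
            logistic, uniq, acc, p0=list(init), xtol=tol, ftol=tol, maxfev=max_nfev
        )
        converged = True
    except RuntimeError:
        logger.warning("fit_psychometric: did not converge")
        popt, converged = np.asarray(init, dtype=float), False
    resid = acc - logistic(uniq, *popt)
    return PsychometricFit(
        a=float(popt[0]),
        b=float(popt[1]),
        c=float(popt[2]),
        d=float(popt[3]),
        converged=converged,
        residual_ss=float(np.sum(resid**2)),
    )


def threshold_levels(angle: float) -> str:
    """Classify an angle: sub (1.5–4.5), supra (7.5–15), or excluded (6)."""
    x = abs(float(angle))
    if not any(math.isclose(x, a, abs_tol=1e-6) for a in PARADIGM_ANGLES):
        raise ValueError(f"angle {angle} not in the paradigm set")
    if 1.5 - 1e-9 <= x <= 4.5 + 1e-9:
        return "sub"
    if 7.5 - 1e-9 <= x <= 15 + 1e-9:
        return "supra"
    return "excluded"


def rt_cv(rts: Sequence[float]) -> float:
    """Reaction-time coefficient of variation: 100 * sd(RT) / mean(RT)."""
    r = np.asarray(rts, dtype=float)
    if r.size < 2:
        raise ValueError("need >= 2 reaction times")
    m = r.mean()
    if m <= 0:
        raise ValueError("mean RT must be positive")
    return float(100.0 * r.std(ddof=1) / m)


def rt_filter(rts: Sequence[float], lo: float = 0.1, hi: float = 2.0) -> np.ndarray:
    """Boolean keep-mask: True unless RT < lo or RT > hi (strict bounds)."""
    r = np.asarray(rts, dtype=float)
    keep = ~((r < lo) | (r > hi))
    n_out = int((~keep).sum())
    if n_out:
        logger.info("rt_filter: excluded %d/%d RT outlier(s)", n_out, r.size)
    return keep


def state_summary(trials: pd.DataFrame, state_col: str = "state_true") -> pd.DataFrame:
    """Per state × threshold-level summary: accuracy %, RT mean/sd/CV.

    RT outliers are removed with the standard bounds first; the 6 deg
    angles fall in neither threshold group and are dropped.
    """
    df = trials.copy()
    df = df[rt_filter(df["rt"].to_numpy())]
    df["level"] = df["tilt"].map(threshold_levels)
    df = df[df["level"] != "excluded"]
    rows = []
    for (state, level), grp in df.groupby([state_col, "level"]):
        rows.append(
            {
                "state": state,
                "level": level,
                "n": len(grp),
                "accuracy_pct": 100.0 * grp["correct"].mean(),
                "rt_mean_ms": 1000.0 * grp["rt"].mean(),
                "rt_sd_ms": 1000.0 * grp["rt"].std(ddof=1),
                "rt_cv": rt_cv(grp["rt"].to_numpy()) if len(grp) >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _pairwise_label_surrogate(
    wide: pd.DataFrame, n_iter: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Post-hoc paired t for every pair of columns, with p from a
    within-subject label-reshuffle surrogate and FDR across the pairs."""
    cols = list(wide.columns)
    pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1 :]]
    arr = wide.to_numpy()  # (n_subjects, n_levels)
    n_sub = arr.shape[0]

    def _ts(m: np.ndarray) -> np.ndarray:
        out = np.empty(len(pairs))
        for k, (a, b) in enumerate(pairs):
            d = m[:, cols.index(a)] - m[:, cols.index(b)]
            sd = d.std(ddof=1)
            out[k] = 0.0 if sd == 0 else d.mean() / (sd / np.sqrt(n_sub))
        return out

    t_obs = _ts(arr)
    null = np.empty((n_iter, len(pairs)))
    for it in range(n_iter):
        shuffled = arr.copy()
        for s in range(n_sub):
            rng.shuffle(shuffled[s])
        null[it] = _ts(shuffled)
    p = surrogate_p(np.abs(t_obs), np.abs(null))
    q = fdr_bh(p)
    return pd.DataFrame(
        {"pair": [f"{a}_vs_{b}" for a, b in pairs], "t": t_obs, "p": p, "q": q}
    )


def behavior_tests(
    data: pd.DataFrame,
    dv: str,
    factor_a: str,
    factor_b: str | None = None,
    n_iter: int = 1000,
    seed: int | None = None,
) -> dict:
    """State-wise behavioral ANOVA with surrogate p and post-hoc tests.

    ``data`` is long format with one row per subject × cell and a
    ``subject`` column.  F statistics for the main effect(s) and the
    interaction carry both the parametric p and a surrogate p obtained by
    reshuffling factor-A labels within subject in ``n_iter`` runs.
    Post-hoc paired t-tests across all factor-A level pairs are FDR
    corrected.  An empty cell raises an error naming the cell.
    """
    if "subject" not in data.columns:
        raise ValueError("data needs a 'subject' column")
    subjects = data["subject"].unique()
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects")
    y = data[dv].to_numpy(dtype=float)
    fa = data[factor_a].to_numpy()
    fb = data[factor_b].to_numpy() if factor_b else None
    try:
        obs = anova_f(y, fa, fb)
    except ValueError as err:
        if "empty cell" in str(err):
            raise ValueError(f"empty design cell for factors {factor_a}/{factor_b}") from err
        raise

    rng = np.random.default_rng(seed)
    effects = list(obs)
    null = {e: np.empty(n_iter) for e in effects}
    subj_codes = data["subject"].to_numpy()
    # strata preserve design balance: factor-A labels are reshuffled within
    # subject (and within each factor-B level when present)
    strata = [
        (subj_codes == s) & (np.ones_like(subj_codes, bool) if fb is None else fb == lev)
        for s in subjects
        for lev in ([None] if fb is None else pd.unique(fb))
    ]
    for it in range(n_iter):
        fa_s = fa.copy()
        for m in strata:
            fa_s[m] = rng.permutation(fa_s[m])
        res = anova_f(y, fa_s, fb)
        for e in effects:
            null[e][it] = res[e].statistic

    out: dict = {}
    for e in effects:
        p_surr = float(surrogate_p(np.asarray(obs[e].statistic), null[e]))
        out[e] = {
            "parametric": obs[e],
            "surrogate_p": p_surr,
        }

    # post-hoc over factor-A levels, within each level of factor B (or overall)
    posthoc = {}
    rng2 = np.random.default_rng(None if seed is None else seed + 1)
    if factor_b is None:
        wide = data.pivot_table(index="subject", columns=factor_a, values=dv)
        posthoc["overall"] = _pairwise_label_surrogate(wide.dropna(), n_iter, rng2)
    else:
        for lev in pd.unique(fb):
            sub = data[data[factor_b] == lev]
            wide = sub.pivot_table(index="subject", columns=factor_a, values=dv)
            posthoc[str(lev)] = _pairwise_label_surrogate(wide.dropna(), n_iter, rng2)
    out["posthoc"] = posthoc
    return out
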