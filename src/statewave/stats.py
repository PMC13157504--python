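"""Shared statistical machinery.

Surrogate/permutation engines (circular shift, label permutation, subject
reassignment), Benjamini–Hochberg FDR, classical ANOVA F from sums of
squares, and correlation primitives.  Every empirical null uses the add-one
p convention ``p = (1 + #{null >= observed}) / (1 + n_iter)`` so p is never
exactly zero; all engines are reproducible bit-for-bit given a seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurrogateDistribution",
    "TestResult",
    "fdr_bh",
    "normal_tail",
    "correlation",
    "anova_f",
    "permutation_null",
    "circular_shift_surrogate",
    "surrogate_p",
    "paired_t",
]

Tails = Literal["two", "one"]

#: Cap on the number of distinct label assignments below which a permutation
#: null is enumerated exactly instead of sampled.
EXACT_ENUMERATION_LIMIT = 10_000


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p: float
    df: tuple[float, ...] | None = None
    q: float | None = None
    tails: Tails = "two"
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "statistic": float(self.statistic),
            "df": None if self.df is None else list(self.df),
            "p": float(self.p),
            "q": None if self.q is None else float(self.q),
            "tails": self.tails,
        }


@dataclass
class SurrogateDistribution:
    """Observed statistic with its empirical null distribution."""

    observed: np.ndarray  # scalar () or series (T,)
    null_values: np.ndarray  # (n_iter,) or (n_iter, T)
    scheme: str
    seed: int | None = None
    exact: bool = False
    p: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.null_values = np.asarray(self.null_values, dtype=float)
        if not self.exact and self.null_values.shape[0] < 100:
            raise ValueError(
                f"need >= 100 surrogate iterations, got {self.null_values.shape[0]}"
            )
        self.p = surrogate_p(self.observed, self.null_values)

    @property
    def n_iter(self) -> int:
        return int(self.null_values.shape[0])


def surrogate_p(observed: np.ndarray, null_values: np.ndarray) -> np.ndarray:
    """Add-one empirical p-value, one draw per row of ``null_values``.

    One-sided (greater): callers wanting two-sided behaviour pass absolute
    values of both the observed statistic and the null draws.
    """
    observed = np.asarray(observed, dtype=float)
    null_values = np.asarray(null_values, dtype=float)
    n_iter = null_values.shape[0]
    exceed = np.sum(null_values >= observed[None, ...], axis=0)
    return (1.0 + exceed) / (1.0 + n_iter)


def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (q), input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def normal_tail(z: float) -> float:
    """Two-sided standard-normal tail probability ``2 * (1 - Phi(z))``."""
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    return float(2.0 * sps.norm.sf(z))


def correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["pearson", "spearman"] = "pearson",
) -> TestResult:
    """Pearson or Spearman correlation with a two-tailed parametric p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(statistic=float(r), p=float(p), df=(float(x.size - 2),), label=method)


def paired_t(a: Sequence[float], b: Sequence[float], tails: Tails = "two") -> TestResult:
    """Paired-samples t-test; one-tailed variant tests mean(a) > mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    d = a - b
    if d.std(ddof=1) == 0.0:
        # degenerate: identical pairs give t = 0; constant nonzero shift, inf
        t = 0.0 if d.mean() == 0 else math.copysign(math.inf, d.mean())
        p = 1.0 if t == 0 else 0.0
    else:
        t, p = sps.ttest_rel(a, b)
    if tails == "one":
        p = p / 2.0 if t > 0 else 1.0 - p / 2.0
    return TestResult(statistic=float(t), p=float(p), df=(float(a.size - 1),), tails=tails)


# ---------------------------------------------------------------------------
# ANOVA


def _codes(factor: Sequence) -> tuple[np.ndarray, int]:
    vals, codes = np.unique(np.asarray(factor), return_inverse=True)
    return codes, len(vals)


def anova_f(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence | None = None,
) -> dict[str, TestResult]:
    """Classical fixed-effects ANOVA F statistics from sums of squares.

    One-way (``factor_b`` omitted) allows unequal group sizes; the two-way
    crossed layout requires a balanced design (equal cell counts) and returns
    main effects ``A``, ``B`` and the ``AxB`` interaction.  Cells with zero
    within-cell variance but unequal means yield an infinite F, which is
    returned as ``inf`` with ``p = 0.0`` and left to the caller to flag.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.size == 0 or not np.all(np.isfinite(y)):
        raise ValueError("values must be a finite 1-D array")
    ca, na = _codes(factor_a)
    if ca.shape != y.shape:
        raise ValueError("factor_a length mismatch")
    grand = y.mean()

    if factor_b is None:
        if na < 2:
            raise ValueError("one-way ANOVA needs >= 2 groups")
        counts = np.bincount(ca, minlength=na)
        if np.any(counts == 0):
            raise ValueError("empty group")
        group_means = np.bincount(ca, weights=y, minlength=na) / counts
        ss_between = float(np.sum(counts * (group_means - grand) ** 2))
        ss_within = float(np.sum((y - group_means[ca]) ** 2))
        df_b, df_w = na - 1, y.size - na
        return {"A": _f_result(ss_between, df_b, ss_within, df_w, "A")}

    cb, nb = _codes(factor_b)
    if cb.shape != y.shape:
        raise ValueError("factor_b length mismatch")
    cell = ca * nb + cb
    counts = np.bincount(cell, minlength=na * nb)
    if np.any(counts == 0):
        bad = int(np.argmin(counts))
        raise ValueError(f"empty cell (a={bad // nb}, b={bad % nb})")
    if len(set(counts.tolist())) != 1:
        raise ValueError("two-way ANOVA requires a balanced design")
    n_cell = int(counts[0])

    cell_means = np.bincount(cell, weights=y, minlength=na * nb) / counts
    a_means = cell_means.reshape(na, nb).mean(axis=1)
    b_means = cell_means.reshape(na, nb).mean(axis=0)
    ss_a = n_cell * nb * float(np.sum((a_means - grand) ** 2))
    ss_b = n_cell * na * float(np.sum((b_means - grand) ** 2))
    inter = cell_means.reshape(na, nb) - a_means[:, None] - b_means[None, :] + grand
    ss_ab = n_cell * float(np.sum(inter**2))
    ss_e = float(np.sum((y - cell_means[cell]) ** 2))
    df_e = na * nb * (n_cell - 1)
    return {
        "A": _f_result(ss_a, na - 1, ss_e, df_e, "A"),
        "B": _f_result(ss_b, nb - 1, ss_e, df_e, "B"),
        "AxB": _f_result(ss_ab, (na - 1) * (nb - 1), ss_e, df_e, "AxB"),
    }


def _f_result(ss_effect: float, df_effect: int, ss_err: float, df_err: int, label: str) -> TestResult:
    if df_err <= 0:
        raise ValueError("no error degrees of freedom (one observation per cell)")
    ms_err = ss_err / df_err
    if ms_err == 0.0:
        f = math.inf if ss_effect > 0 else 0.0
        p = 0.0 if ss_effect > 0 else 1.0
    else:
        f = (ss_effect / df_effect) / ms_err
        p = float(sps.f.sf(f, df_effect, df_err))
    return TestResult(statistic=float(f), p=p, df=(float(df_effect), float(df_err)), label=label)


# ---------------------------------------------------------------------------
# Permutation / surrogate engines


def _two_group_assignments(n_total: int, n_group1: int) -> int:
    return math.comb(n_total, n_group1)


def permutation_null(
    values: Sequence[float],
    labels: Sequence,
    statistic: Callable[[np.ndarray, np.ndarray], float],
    n_iter: int = 1000,
    seed: int | None = None,
    tails: Tails = "two",
) -> SurrogateDistribution:
    """Label-permutation null for a statistic of ``(values, labels)``.

    ``statistic`` receives the value array and an integer label-code array.
    For a two-group design with at most :data:`EXACT_ENUMERATION_LIMIT`
    distinct assignments the null is enumerated exactly (every assignment
    once) instead of sampled, and the p-value is the exact permutation p.
    Two-tailed tests compare absolute statistic values.
    """
    y = np.asarray(values, dtype=float)
    codes, n_levels = _codes(labels)
    if n_levels < 2:
        raise ValueError("need >= 2 distinct labels")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")

    obs = float(statistic(y, codes))
    transform = abs if tails == "two" else float

    if n_levels == 2:
        n1 = int(np.sum(codes == 1))
        n_assign = _two_group_assignments(y.size, n1)
        if n_assign <= EXACT_ENUMERATION_LIMIT:
            null = np.empty(n_assign)
            perm = np.zeros(y.size, dtype=int)
            for i, idx in enumerate(itertools.combinations(range(y.size), n1)):
                perm[:] = 0
                perm[list(idx)] = 1
                null[i] = transform(statistic(y, perm))
            dist = SurrogateDistribution(
                observed=np.asarray(transform(obs)),
                null_values=null,
                scheme="label_permutation_exact",
                seed=seed,
                exact=True,
            )
            # exact p: no add-one correction needed, every assignment counted once
            dist.p = np.asarray(np.mean(null >= transform(obs)))
            dist.observed = np.asarray(obs)
            return dist

    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        null[i] = transform(statistic(y, rng.permutation(codes)))
    dist = SurrogateDistribution(
        observed=np.asarray(transform(obs)),
        null_values=null,
        scheme="label_permutation",
        seed=seed,
    )
    dist.observed = np.asarray(obs)
    return dist


def circular_shift_surrogate(
    series: np.ndarray,
    statistic: Callable[[np.ndarray], np.ndarray],
    n_iter: int = 1000,
    shift_range: tuple[int, int] | None = None,
    seed: int | None = None,
) -> SurrogateDistribution:
    """Circular-shift surrogate over per-subject time series.

    ``series`` is (n_subjects, n_times).  Each iteration rotates every
    subject's series by an independent uniform offset (wrap-around), which
    preserves each subject's power spectrum exactly while destroying event
    alignment, then recomputes ``statistic`` (a function of the shifted
    (n_subjects, n_times) array, typically the group mean series).
    ``shift_range`` limits offsets to ``[lo, hi]`` samples (inclusive);
    default is the full series length.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] < 2:
        raise ValueError("series must be (n_subjects, n_times) with n_times > 1")
    n_sub, n_t = series.shape
    if shift_range is None:
        lo, hi = 0, n_t - 1
    else:
        lo, hi = int(shift_range[0]), int(shift_range[1])
        if hi - lo > n_t:
            raise ValueError("shift range longer than the series")
    rng = np.random.default_rng(seed)
    observed = np.asarray(statistic(series), dtype=float)
    null = np.empty((n_iter,) + observed.shape)
    rows = np.arange(n_t)
    for i in range(n_iter):
        shifts = rng.integers(lo, hi + 1, size=n_sub)
        idx = (rows[None, :] - shifts[:, None]) % n_t
        shifted = np.take_along_axis(series, idx, axis=1)
        null[i] = statistic(shifted)
    return SurrogateDistribution(
        observed=observed, null_values=null, scheme="circular_shift", seed=seed
    )
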