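"""Statistical core: FDR, ANOVA, correlation, permutation and circular-shift
surrogates, tail probabilities."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from statewave import stats


# ---------------------------------------------------------------------------
# Benjamini–Hochberg


def bh_stepup_oracle(p):
    """Brute-force BH step-up: q_i = min over j with p_(j) >= p_(i) of
    m * p_(j) / rank(j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def test_fdr_single_p_is_unchanged():
    assert stats.fdr_bh([0.03]) == pytest.approx([0.03])


def test_fdr_worked_example():
    q = stats.fdr_bh([0.01, 0.02, 0.03, 0.04])
    assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_fdr_equal_ps_stay_equal():
    q = stats.fdr_bh([0.2, 0.2, 0.2])
    assert q == pytest.approx([0.2, 0.2, 0.2])


def test_fdr_rejects_invalid_p():
    with pytest.raises(ValueError):
        stats.fdr_bh([0.0, 0.5])
    with pytest.raises(ValueError):
        stats.fdr_bh([1.5])


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
        min_size=1,
        max_size=8,
    )
)
def test_fdr_matches_bruteforce_stepup_for_short_vectors(p):
    assert stats.fdr_bh(p) == pytest.approx(bh_stepup_oracle(p), abs=1e-12)


def test_fdr_monotone_in_sorted_order():
    rng = np.random.default_rng(0)
    p = rng.uniform(1e-6, 1, size=40)
    q = stats.fdr_bh(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all(q >= p - 1e-12)


# ---------------------------------------------------------------------------
# Normal tail


def test_normal_tail_at_channel_criterion():
    assert round(stats.normal_tail(3.0), 4) == 0.0027


@pytest.mark.parametrize(
    "z,expected", [(0.0, 1.0), (1.959964, 0.05)]
)
def test_normal_tail_reference_points(z, expected):
    assert round(stats.normal_tail(z), 4) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Correlation


def test_pearson_perfect_linear():
    x = np.arange(10.0)
    res = stats.correlation(x, 2 * x + 1)
    assert res.statistic == pytest.approx(1.0)


def test_spearman_monotone_nonlinear_beats_pearson():
    x = np.linspace(0.1, 3, 15)
    y = np.exp(3 * x)
    rho = stats.correlation(x, y, method="spearman").statistic
    r = stats.correlation(x, y, method="pearson").statistic
    assert rho == pytest.approx(1.0)
    assert r < 1.0


def test_spearman_matches_rank_formula_on_small_set():
    x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
    y = np.array([9.0, 2.0, 6.0, 5.0, 3.0])
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho_brute = np.corrcoef(rx, ry)[0, 1]
    assert stats.correlation(x, y, method="spearman").statistic == pytest.approx(rho_brute)


# ---------------------------------------------------------------------------
# ANOVA


def test_oneway_f_equals_t_squared_for_two_groups(rng):
    a = rng.normal(0, 1, 12)
    b = rng.normal(0.8, 1, 15)
    f = stats.anova_f(np.r_[a, b], ["a"] * 12 + ["b"] * 15)["A"]
    t, p = sps.ttest_ind(a, b)
    assert f.statistic == pytest.approx(t**2)
    assert f.p == pytest.approx(p)


def test_twoway_f_matches_statsmodels(rng):
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    n = 8
    rows = []
    for a in ("x", "y"):
        for b in ("u", "v", "w"):
            for _ in range(n):
                rows.append({"A": a, "B": b, "y": rng.normal(hash((a, b)) % 5, 1)})
    df = pd.DataFrame(rows)
    ours = stats.anova_f(df["y"], df["A"], df["B"])
    table = sm.stats.anova_lm(ols("y ~ C(A) * C(B)", data=df).fit(), typ=2)
    assert ours["A"].statistic == pytest.approx(table.loc["C(A)", "F"])
    assert ours["B"].statistic == pytest.approx(table.loc["C(B)", "F"])
    assert ours["AxB"].statistic == pytest.approx(table.loc["C(A):C(B)", "F"])


def test_anova_zero_within_cell_variance_flagged():
    y = [1.0, 1.0, 2.0, 2.0]
    res = stats.anova_f(y, ["a", "a", "b", "b"])["A"]
    assert np.isinf(res.statistic)
    assert res.p == 0.0


def test_anova_empty_cell_rejected():
    with pytest.raises(ValueError, match="empty cell"):
        stats.anova_f([1.0, 2.0, 3.0], ["a", "a", "b"], ["u", "v", "u"])


# ---------------------------------------------------------------------------
# Permutation null


def mean_diff(values, codes):
    return values[codes == 1].mean() - values[codes == 0].mean()


def test_permutation_exact_enumeration_matches_itertools_oracle(rng):
    y = rng.normal(0, 1, 9)
    labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1])
    dist = stats.permutation_null(y, labels, mean_diff, n_iter=100, tails="two")
    assert dist.exact
    obs = abs(mean_diff(y, labels))
    count = 0
    total = 0
    for idx in itertools.combinations(range(9), 5):
        perm = np.zeros(9, dtype=int)
        perm[list(idx)] = 1
        total += 1
        if abs(mean_diff(y, perm)) >= obs:
            count += 1
    assert float(dist.p) == pytest.approx(count / total)


def test_permutation_label_invariant_statistic_gives_p_one(rng):
    y = rng.normal(0, 1, 8)
    dist = stats.permutation_null(
        y, [0, 0, 0, 0, 1, 1, 1, 1], lambda v, c: float(v.sum()), n_iter=100
    )
    assert float(dist.p) == pytest.approx(1.0)


def test_permutation_complete_separation_gives_minimal_p():
    y = np.r_[np.zeros(6), np.ones(6) + 10]
    labels = np.r_[np.zeros(6), np.ones(6)].astype(int)
    dist = stats.permutation_null(y, labels, mean_diff, n_iter=100, tails="two")
    # exact enumeration: only the two extreme assignments reach |obs|
    assert float(dist.p) <= 2.0 / 924 + 1e-12


def test_permutation_monte_carlo_path_reproducible(rng):
    y = rng.normal(0, 1, 30)
    labels = (np.arange(30) % 2).astype(int)
    d1 = stats.permutation_null(y, labels, mean_diff, n_iter=150, seed=5)
    d2 = stats.permutation_null(y, labels, mean_diff, n_iter=150, seed=5)
    assert np.array_equal(d1.null_values, d2.null_values)
    assert d1.scheme == "label_permutation"


# ---------------------------------------------------------------------------
# Circular shift surrogate


def test_circular_shift_preserves_power_spectrum(rng):
    x = rng.normal(0, 1, (1, 128))
    spectra = []

    def stat(s):
        spectra.append(np.abs(np.fft.rfft(s[0])) ** 2)
        return s.mean(axis=0)

    stats.circular_shift_surrogate(x, stat, n_iter=100, seed=0)
    base = np.abs(np.fft.rfft(x[0])) ** 2
    for sp in spectra[1:]:
        assert sp == pytest.approx(base, rel=1e-9)


def test_circular_shift_constant_series_degenerate_null():
    x = np.full((3, 50), 2.5)
    dist = stats.circular_shift_surrogate(x, lambda s: s.mean(axis=0), n_iter=100, seed=1)
    assert np.allclose(dist.null_values, dist.observed)


def test_circular_shift_null_sd_matches_iid_theory(rng):
    # statistic: cross-subject mean at one fixed time point; for white noise
    # the surrogate null sd is sigma / sqrt(n_subjects)
    n_sub, n_t, sigma = 8, 4096, 1.3
    x = rng.normal(0, sigma, (n_sub, n_t))
    dist = stats.circular_shift_surrogate(
        x, lambda s: np.asarray(s[:, 0].mean()), n_iter=800, seed=2
    )
    assert dist.null_values.std() == pytest.approx(sigma / np.sqrt(n_sub), rel=0.12)


def test_surrogate_p_add_one_convention():
    p = stats.surrogate_p(np.asarray(1.0), np.array([0.5, 1.5, 0.7, 2.0]))
    assert float(p) == pytest.approx((1 + 2) / (1 + 4))
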