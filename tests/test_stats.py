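"""Statistical layer: oracle agreement, exact-test enumeration, worked
examples and the PCA plate-effect verdict."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from somaqc.stats import (
    median_iqr,
    pca_plate_assoc,
    pearson,
    t_test,
    wilcoxon_rank_sum,
)

# ---------------------------------------------------------------------------
# Pearson


def test_pearson_perfect_linear():
    x = np.arange(10.0)
    r, p = pearson(x, 2 * x + 1)
    assert r == 1.0 and p == 0.0
    r, p = pearson(x, -x)
    assert r == -1.0 and p == 0.0


def test_pearson_worked_vector():
    # frozen from the closed-form computation: r = 10/sqrt(10*14.8)
    r, p = pearson([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
    assert r == pytest.approx(10 / np.sqrt(10 * 14.8), abs=1e-12)
    assert r == pytest.approx(0.8219949365267865, abs=1e-12)
    assert p == pytest.approx(0.08770664700806553, abs=1e-12)


def test_pearson_p_formula_at_r08_n5():
    # t = r*sqrt(n-2)/sqrt(1-r^2) = 0.8*sqrt(3)/0.6 = 2.3094, p = 0.1041
    t = 0.8 * np.sqrt(3) / np.sqrt(1 - 0.64)
    assert t == pytest.approx(2.3094010767585034)
    assert 2 * sps.t.sf(t, 3) == pytest.approx(0.10408803866182778, abs=1e-12)


def test_pearson_matches_scipy_on_random_vectors():
    rng = np.random.default_rng(123)
    for _ in range(300):
        n = rng.integers(3, 40)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        r, p = pearson(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_pearson_affine_invariance():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=20), rng.normal(size=20)
    r0, _ = pearson(x, y)
    r1, _ = pearson(3.0 * x + 7.0, y)
    r2, _ = pearson(x, -2.0 * y + 1.0)
    assert r1 == pytest.approx(r0, abs=1e-12)
    assert r2 == pytest.approx(-r0, abs=1e-12)


def test_pearson_degenerate_inputs():
    with pytest.raises(ValueError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        pearson([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# rank-sum test


def _brute_force_rank_sum_p(x, y):
    """Independent oracle: enumerate every assignment of the pooled values
    to the two groups and accumulate the exact two-sided tail."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for combo in itertools.combinations(range(n), nx):
        u = ranks[list(combo)].sum() - nx * (nx + 1) / 2
        us.append(u)
    us = np.asarray(us)
    lower = np.mean(us <= u_obs + 1e-9)
    upper = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


def test_wilcoxon_most_extreme_arrangement():
    u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(2 / 20, abs=1e-12)


def test_wilcoxon_identical_groups_p_one():
    _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0)


def test_wilcoxon_exact_equals_enumeration_all_small_sizes():
    """For every tie-free (nx, ny) with nx, ny <= 7 the exact p equals the
    brute-force enumeration to 1e-12."""
    rng = np.random.default_rng(2024)
    for nx in range(1, 8):
        for ny in range(1, 8):
            vals = rng.permutation(np.arange(1.0, nx + ny + 1.0))
            x, y = vals[:nx], vals[nx:]
            u, p = wilcoxon_rank_sum(x, y, method="exact")
            assert p == pytest.approx(_brute_force_rank_sum_p(x, y), abs=1e-12)


def test_wilcoxon_exact_matches_scipy():
    rng = np.random.default_rng(7)
    for _ in range(30):
        nx, ny = rng.integers(2, 8, size=2)
        vals = rng.permutation(np.arange(float(nx + ny))) + rng.normal(0, 0.01, nx + ny)
        x, y = vals[:nx], vals[nx:]
        u, p = wilcoxon_rank_sum(x, y, method="exact")
        ref = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_wilcoxon_normal_approx_matches_scipy_asymptotic():
    rng = np.random.default_rng(11)
    x = rng.normal(size=12)
    y = rng.normal(size=15)
    u, p = wilcoxon_rank_sum(x, y)  # auto -> normal above 14
    ref = sps.mannwhitneyu(x, y, method="asymptotic", alternative="two-sided")
    assert u == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue, rel=1e-12)


def test_wilcoxon_tie_correction_matches_scipy():
    x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 9.0]
    y = [2.0, 2.0, 4.0, 5.0, 6.0, 6.0, 7.0, 7.0, 8.0]
    u, p = wilcoxon_rank_sum(x, y)
    ref = sps.mannwhitneyu(x, y, method="asymptotic", alternative="two-sided")
    assert p == pytest.approx(ref.pvalue, rel=1e-12)


def test_wilcoxon_empty_group_raises():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


@settings(max_examples=30, deadline=None)
@given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 10_000))
def test_wilcoxon_exact_oracle_property(nx, ny, seed):
    rng = np.random.default_rng(seed)
    vals = rng.permutation(np.arange(1.0, nx + ny + 1.0))
    x, y = vals[:nx], vals[nx:]
    _, p = wilcoxon_rank_sum(x, y, method="exact")
    assert p == pytest.approx(_brute_force_rank_sum_p(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# t test


def test_t_identical_groups():
    t, p = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == pytest.approx(1.0)


def test_t_zero_pooled_variance_raises():
    with pytest.raises(ValueError):
        t_test([0.0, 0.0], [1.0, 1.0])


def test_t_matches_scipy_oracle():
    rng = np.random.default_rng(3)
    for _ in range(200):
        nx, ny = rng.integers(2, 25, size=2)
        x = rng.normal(0, 1, nx)
        y = rng.normal(0.3, 1.4, ny)
        t, p = t_test(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)
        tw, pw = t_test(x, y, variant="welch")
        refw = sps.ttest_ind(x, y, equal_var=False)
        assert tw == pytest.approx(refw.statistic, abs=1e-12)
        assert pw == pytest.approx(refw.pvalue, abs=1e-12)


# ---------------------------------------------------------------------------
# median / IQR


def test_median_iqr_worked_examples():
    assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)
    assert median_iqr([7.0]) == (7.0, 7.0, 7.0)
    with pytest.raises(ValueError):
        median_iqr([])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
def test_median_iqr_ordering(values):
    med, q25, q75 = median_iqr(values)
    assert q25 <= med <= q75


# ---------------------------------------------------------------------------
# PCA plate association


def test_pca_single_plate_not_applicable():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(10, 5))
    res = pca_plate_assoc(X, ["P1"] * 10)
    assert res.verdict == "not applicable"


def test_pca_variance_fractions_valid():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(12, 6))
    res = pca_plate_assoc(X, ["P1"] * 6 + ["P2"] * 6, k=6)
    vf = res.variance_explained
    assert all(0 <= v <= 1 for v in vf)
    assert all(vf[i] >= vf[i + 1] - 1e-12 for i in range(len(vf) - 1))
    assert sum(vf) == pytest.approx(1.0)  # k = full rank


def test_pca_detects_strong_plate_shift():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 30)) * 0.3
    X[10:] += rng.normal(2.0, 0.5, size=30)  # per-analyte plate-2 offsets
    res = pca_plate_assoc(X, ["P1"] * 10 + ["P2"] * 10)
    assert res.detected
    assert res.p_values[0] < 0.01


def test_pca_k_exceeds_rank_raises():
    with pytest.raises(ValueError):
        pca_plate_assoc(np.ones((3, 2)), ["P1", "P1", "P2"], k=5)
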