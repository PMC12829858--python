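from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ffaconcord.io import SampleTable
from ffaconcord.stats import (ComparisonPolicy, adjust_for_covariates,
                              assess_normality, chi_square_contingency,
                              compare_two_groups, contingency_consistency,
                              kruskal_wallis, one_way_anova,
                              significance_stars, sucrose_preference)

NONPARAMETRIC = ComparisonPolicy(force="mann_whitney")


# ---------------------------------------------------------------- oracles
def mann_whitney_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Conditions on the observed pooled values; U counts pairs (xi > yj) plus
    half-ties; two-sided p is the fraction of assignments whose U deviates
    from its null mean at least as much as the observed U.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        gt = (xs[:, None] > ys[None, :]).sum()
        eq = (xs[:, None] == ys[None, :]).sum()
        return gt + 0.5 * eq

    mean_u = n1 * (len(y)) / 2.0
    u_obs = u_stat(range(n1))
    dev_obs = abs(u_obs - mean_u)
    devs = [abs(u_stat(idx) - mean_u)
            for idx in combinations(range(len(pooled)), n1)]
    p = np.mean([d >= dev_obs - 1e-12 for d in devs])
    return u_obs, p


def chi2_brute_force(counts):
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    return ((counts - expected) ** 2 / expected).sum()


# ------------------------------------------------------------- normality
def test_constant_group_is_untestable():
    rep = assess_normality({"a": [5, 5, 5, 5], "b": [1, 2, 3, 4]})
    assert rep.verdict == "untestable"


def test_normal_draw_passes_screen():
    rng = np.random.default_rng(7)
    rep = assess_normality({"a": rng.standard_normal(200),
                            "b": rng.standard_normal(200)})
    assert rep.verdict == "normal"
    for g in rep.groups:
        assert 0 < g.W <= 1
        assert len(g.qq) == 200


def test_exponential_draw_fails_screen():
    rng = np.random.default_rng(7)
    rep = assess_normality({"a": rng.exponential(1.0, 200),
                            "b": rng.exponential(1.0, 200)})
    assert rep.verdict == "non_normal"


# ------------------------------------------------------- two-group tests
def test_separated_groups_exact_mann_whitney():
    res = compare_two_groups([1, 2, 3], [4, 5, 6], NONPARAMETRIC)
    u_oracle, p_oracle = mann_whitney_enumeration(
        np.array([1., 2, 3]), np.array([4., 5, 6]))
    assert res.test_used == "mann_whitney"
    assert res.statistic == u_oracle == 0
    assert res.p_value == pytest.approx(p_oracle) == pytest.approx(0.1)
    assert res.direction == "down"


def test_identical_groups_p_one_direction_none():
    res = compare_two_groups([1, 2, 3], [1, 2, 3], NONPARAMETRIC)
    assert res.p_value == pytest.approx(1.0)
    assert res.direction == "none"
    assert not res.significant


def test_all_tied_values():
    res = compare_two_groups([2, 2, 2], [2, 2], NONPARAMETRIC)
    assert res.p_value == 1.0
    assert res.direction == "none"


def test_too_small_group_raises():
    with pytest.raises(ValueError):
        compare_two_groups([1.0], [1, 2, 3])


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(2, 6), st.integers(2, 6), st.integers(0, 10_000))
def test_exact_branch_matches_enumeration(n1, n2, seed):
    """The exact Mann-Whitney branch agrees with full enumeration (n <= 8)."""
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=n1), rng.normal(1.0, size=n2)
    res = compare_two_groups(x, y, NONPARAMETRIC)
    u_oracle, p_oracle = mann_whitney_enumeration(x, y)
    assert res.p_value == pytest.approx(p_oracle, abs=1e-12)


def test_normal_data_routes_to_t_test():
    rng = np.random.default_rng(5)
    res = compare_two_groups(rng.normal(size=50), rng.normal(2, 1, 50))
    assert res.test_used == "t_test"
    assert res.significant
    assert res.direction == "down"


def test_welch_vs_student_flag():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=20), rng.normal(0, 5, size=10)
    welch = compare_two_groups(x, y, ComparisonPolicy(force="t_test"))
    student = compare_two_groups(
        x, y, ComparisonPolicy(force="t_test", parametric="student"))
    assert welch.p_value != student.p_value


# ------------------------------------------------------------ chi-square
def test_chi_square_matches_brute_force():
    rng = np.random.default_rng(3)
    for _ in range(20):
        counts = rng.integers(1, 60, size=(2, 3))
        stat, df, p = chi_square_contingency(counts)
        assert stat == pytest.approx(chi2_brute_force(counts), abs=1e-10)
        assert df == 2


def test_chi_square_independence_is_zero():
    stat, df, p = chi_square_contingency([[10, 10], [10, 10]])
    assert stat == 0.0
    assert p == pytest.approx(1.0)


def test_chi_square_zero_marginal_rejected():
    with pytest.raises(ValueError):
        chi_square_contingency([[0, 0], [5, 5]])


def test_contingency_consistency_flags_mismatch():
    flags = contingency_consistency([[55, 32], [22, 94]], row_totals=[88, 116])
    assert len(flags) == 1 and "88" in flags[0]
    assert contingency_consistency([[55, 33], [22, 94]],
                                   row_totals=[88, 116]) == []


# -------------------------------------------------------- kruskal-wallis
def test_kruskal_wallis_hand_value():
    # ranks 1,2 | 3,4: H = 12/(4*5) * [2*(1.5-2.5)^2 + 2*(3.5-2.5)^2] = 2.4
    H, df, p = kruskal_wallis([[1, 2], [3, 4]])
    assert H == pytest.approx(2.4)
    assert df == 1


def test_kruskal_wallis_identical_groups():
    H, df, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
    assert H == pytest.approx(0.0, abs=1e-12)


def test_kruskal_wallis_all_constant():
    H, df, p = kruskal_wallis([[5, 5], [5, 5, 5]])
    assert (H, p) == (0.0, 1.0)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_kruskal_wallis_matches_formula_oracle(seed):
    """Tie-corrected H equals the rank-sum formula computed directly."""
    rng = np.random.default_rng(seed)
    groups = [rng.integers(0, 8, size=rng.integers(3, 7)).astype(float)
              for _ in range(3)]
    if np.ptp(np.concatenate(groups)) == 0:
        return
    H, df, p = kruskal_wallis(groups)
    pooled = np.concatenate(groups)
    from scipy.stats import rankdata
    ranks = rankdata(pooled)
    n = len(pooled)
    splits = np.cumsum([len(g) for g in groups])[:-1]
    h = 12 / (n * (n + 1)) * sum(
        len(g) * (r.mean() - (n + 1) / 2) ** 2
        for g, r in zip(groups, np.split(ranks, splits)))
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    assert H == pytest.approx(h / correction, abs=1e-10)


def test_one_way_anova_two_groups_matches_t():
    rng = np.random.default_rng(2)
    x, y = rng.normal(size=10), rng.normal(1, 1, 10)
    F, dfb, dfw, p = one_way_anova([x, y])
    t = compare_two_groups(x, y, ComparisonPolicy(force="t_test",
                                                  parametric="student"))
    assert F == pytest.approx(t.statistic ** 2)
    assert p == pytest.approx(t.p_value)


# ------------------------------------------------- covariate adjustment
def _cov_table(y, covs):
    df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(y))],
                       "group": "g", **covs, "C6:0": y})
    return SampleTable(df, ["C6:0"])


def test_orthogonal_covariate_leaves_values_unchanged():
    table = _cov_table([1.0, 2.0, 3.0], {"age": [0.0, 1.0, 0.0]})
    adjusted, params = adjust_for_covariates(table, ["age"], "C6:0")
    assert np.allclose(adjusted.to_numpy(), [1, 2, 3])
    assert params["age"] == pytest.approx(0.0, abs=1e-12)


def test_perfectly_linear_outcome_collapses_to_mean():
    y = [1.0, 2.0, 3.0, 4.0]
    table = _cov_table(y, {"age": [10.0, 20.0, 30.0, 40.0]})
    adjusted, _ = adjust_for_covariates(table, ["age"], "C6:0")
    assert np.allclose(adjusted.to_numpy(), np.mean(y))


def test_known_sex_effect_recovered():
    rng = np.random.default_rng(9)
    n, beta = 400, 0.5
    sex = rng.integers(0, 2, n)
    y = np.exp(3.0 + beta * sex + rng.normal(0, 0.3, n))
    table = _cov_table(np.log(y), {"sex": np.where(sex, "female", "male")})
    _, params = adjust_for_covariates(table, ["sex"], "C6:0")
    se = 0.3 / np.sqrt(n / 4)
    assert abs(params["sex"] - beta) < 3 * se


def test_adjustment_invariant_to_covariate_rescaling():
    rng = np.random.default_rng(4)
    age = rng.uniform(10, 18, 50)
    y = 2.0 + 0.1 * age + rng.normal(0, 0.5, 50)
    t1 = _cov_table(y, {"age": age})
    t2 = _cov_table(y, {"age": age * 12 + 7})  # months, shifted
    a1, _ = adjust_for_covariates(t1, ["age"], "C6:0")
    a2, _ = adjust_for_covariates(t2, ["age"], "C6:0")
    assert np.allclose(a1.to_numpy(), a2.to_numpy())


def test_collinear_design_raises_with_names():
    rng = np.random.default_rng(1)
    age = rng.uniform(10, 18, 20)
    t = _cov_table(rng.uniform(1, 5, 20),
                   {"age": age, "education_years": 2 * age})
    with pytest.raises(ValueError, match="collinear"):
        adjust_for_covariates(t, ["age", "education_years"], "C6:0")


# ------------------------------------------------------------ behavioral
@pytest.mark.parametrize("sucrose, water, expected", [
    (3.0, 1.0, 75.0),
    (2.0, 2.0, 50.0),
    (0.0, 5.0, 0.0),
])
def test_sucrose_preference(sucrose, water, expected):
    assert sucrose_preference(sucrose, water) == pytest.approx(expected)


def test_sucrose_preference_zero_total_rejected():
    with pytest.raises(ValueError):
        sucrose_preference(0.0, 0.0)


def test_significance_stars():
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == ""
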