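import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tripodd.stats import (
    anova_lsd,
    pearson,
    relative_values,
    significance_stars,
    summarize_cohort,
)


def test_relative_values_divide_by_maximum():
    np.testing.assert_allclose(relative_values([2, 4, 8]), [0.25, 0.5, 1.0])
    np.testing.assert_allclose(relative_values([7.0]), [1.0])


def test_relative_values_all_zero_rejected():
    with pytest.raises(ValueError):
        relative_values([0.0, 0.0])


def test_pearson_perfect_linearity():
    x = np.arange(1.0, 8.0)
    assert pearson(x, 2 * x + 1).statistic == pytest.approx(1.0)
    assert pearson(x, -x).statistic == pytest.approx(-1.0)


def test_pearson_matches_closed_form_covariance():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
    # independent oracle: covariance / (sd_x * sd_y), plus the t-based p-value
    r_oracle = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
    n = x.size
    t = r_oracle * np.sqrt((n - 2) / (1 - r_oracle**2))
    p_oracle = 2 * sps.t.sf(abs(t), n - 2)
    res = pearson(x, y)
    assert res.statistic == pytest.approx(r_oracle, abs=1e-12)
    assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
    assert res.extra["slope"] == pytest.approx(sps.linregress(x, y).slope)


@pytest.mark.parametrize(
    "x,y",
    [([1, 2], [1, 2]), ([1, 2, 3], [5, 5, 5]), ([1, 2, 3], [1, 2])],
)
def test_pearson_invalid_inputs_rejected(x, y):
    with pytest.raises(ValueError):
        pearson(x, y)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    a=st.floats(min_value=0.01, max_value=100),
    b=st.floats(min_value=-100, max_value=100),
)
def test_pearson_invariant_under_positive_affine_transforms(a, b):
    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    y = x + rng.normal(size=20)
    assert pearson(a * x + b, y).statistic == pytest.approx(
        pearson(x, y).statistic, abs=1e-9
    )


def test_identical_groups_give_zero_f():
    res = anova_lsd({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    assert res.statistic == pytest.approx(0.0)


def test_f_equals_t_squared_on_balanced_two_groups():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, 12)
    b = rng.normal(0.7, 1, 12)
    res = anova_lsd({"a": a, "b": b})
    t = sps.ttest_ind(a, b)  # pooled-variance two-sample t
    assert res.statistic == pytest.approx(t.statistic**2, rel=1e-10)
    assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)


def test_three_group_fixture_matches_brute_force_decomposition():
    groups = {"A": [1.0, 2.0, 3.0], "B": [2.0, 3.0, 4.0], "C": [10.0, 11.0, 12.0]}
    res = anova_lsd(groups)
    # brute-force sums of squares
    allv = np.concatenate(list(groups.values()))
    grand = allv.mean()
    ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
    ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
    f_oracle = (ssb / 2) / (ssw / 6)
    assert res.statistic == pytest.approx(f_oracle, rel=1e-12)
    assert res.statistic == pytest.approx(73.0, rel=1e-12)
    assert res.p_value == pytest.approx(sps.f_oneway(*groups.values()).pvalue, rel=1e-9)
    # LSD pairwise oracle: t = diff / sqrt(MSE * (1/n_i + 1/n_j)), df = 6
    mse = ssw / 6
    by_pair = {(c.group_a, c.group_b): c for c in res.pairwise}
    assert set(by_pair) == {("A", "B"), ("A", "C"), ("B", "C")}
    for (ga, gb), cmp_ in by_pair.items():
        diff = np.mean(groups[ga]) - np.mean(groups[gb])
        t_oracle = diff / np.sqrt(mse * (2.0 / 3.0))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), 6)
        assert cmp_.t_statistic == pytest.approx(t_oracle, rel=1e-12)
        assert cmp_.p_value == pytest.approx(p_oracle, rel=1e-12)


def test_ss_decomposition_is_exact():
    rng = np.random.default_rng(6)
    groups = {f"g{i}": rng.normal(i, 2, rng.integers(3, 20)) for i in range(4)}
    res = anova_lsd(groups)
    assert res.extra["ss_total"] == pytest.approx(
        res.extra["ss_between"] + res.extra["ss_within"], abs=1e-9
    )


def test_protected_lsd_suppresses_pairwise_under_null():
    groups = {"a": [1.0, 2.0, 3.0], "b": [1.1, 2.1, 2.9]}
    res = anova_lsd(groups, protected=True)
    assert res.p_value > 0.05
    assert res.pairwise == ()


@pytest.mark.parametrize(
    "groups",
    [{"only": [1.0, 2.0]}, {"a": [1.0], "b": [1.0, 2.0]}],
)
def test_anova_degenerate_groups_rejected(groups):
    with pytest.raises(ValueError):
        anova_lsd(groups)


def test_significance_star_convention():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
    assert significance_stars(0.00009) == "****"


def test_cohort_summary_quartiles_ordered():
    s = summarize_cohort("g", np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
    assert s.lower_quartile <= s.median <= s.upper_quartile
    assert s.n == 5
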