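"""Rank tests, post hocs, OLS and correlation reporting."""

import numpy as np
import pandas as pd
import pytest

from betadelta.group_inference import (
    dunn_bonferroni, kruskal_wallis, normality_gate, ols_fit, pearson_report,
    shapiro_wilk,
)


def test_shapiro_on_normal_scores_is_high():
    from scipy import stats

    scores = stats.norm.ppf((np.arange(1, 21) - 0.5) / 20)
    assert shapiro_wilk(scores)["W"] > 0.99


def test_shapiro_detects_lognormal_skew(rng):
    sample = np.exp(rng.standard_normal(50))
    assert shapiro_wilk(sample)["p"] < 0.05


def test_shapiro_input_validation():
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 2.0])
    with pytest.raises(ValueError):
        shapiro_wilk([3.0] * 10)


def test_normality_gate_small_groups_force_nonparametric(rng):
    values = rng.standard_normal(60)
    gate = normality_gate(values, group_sizes=[20, 20, 20])
    assert gate["small_groups"] and gate["use_nonparametric"]


@pytest.mark.parametrize(
    "groups, expected_h",
    [
        (([1, 2], [3, 4], [5, 6]), 4.5714),
        (([1, 4], [2, 5], [3, 6]), 1.1429),
    ],
)
def test_kruskal_wallis_hand_computed(groups, expected_h):
    res = kruskal_wallis(groups)
    assert res.statistic == pytest.approx(expected_h, abs=1e-4)
    assert res.df == 2


def test_kruskal_wallis_identical_groups_is_zero():
    res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_kruskal_wallis_needs_two_groups():
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2, 3]])


def test_kruskal_wallis_rank_invariance(rng):
    """Any strictly monotone transform of the data leaves H unchanged."""
    groups = [rng.normal(loc, 1, 12) for loc in (0.0, 0.4, 1.0)]
    h0 = kruskal_wallis(groups).statistic
    for transform in (np.exp, lambda v: v ** 3, lambda v: 5 * v - 2):
        h1 = kruskal_wallis([transform(g) for g in groups]).statistic
        assert h1 == pytest.approx(h0, abs=1e-10)


def test_dunn_hand_computed_two_groups():
    (pair,) = dunn_bonferroni([[1, 2], [5, 6]], labels=["lo", "hi"])
    assert pair.z == pytest.approx(-1.549, abs=1e-3)
    assert pair.pair == ("lo", "hi")


def test_dunn_identical_groups_adjusted_p_is_one():
    pairs = dunn_bonferroni([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
    assert all(p.p_adjusted == 1.0 for p in pairs)


def test_dunn_bonferroni_caps_and_multiplies(rng):
    groups = [rng.normal(loc, 1, 10) for loc in (0, 0.2, 3)]
    pairs = dunn_bonferroni(groups)
    assert len(pairs) == 3
    from scipy import stats

    for pr in pairs:
        raw = 2 * stats.norm.sf(abs(pr.z))
        assert pr.p_adjusted == pytest.approx(min(1.0, 3 * raw))


def test_dunn_antisymmetry(rng):
    a, b, c = (rng.normal(loc, 1, 8) for loc in (0, 1, 2))
    z_abc = {p.pair: p.z for p in dunn_bonferroni([a, b, c], labels="ABC")}
    z_cba = {p.pair: p.z for p in dunn_bonferroni([c, b, a], labels="CBA")}
    assert z_abc[("A", "B")] == pytest.approx(-z_cba[("B", "A")])
    assert z_abc[("A", "C")] == pytest.approx(-z_cba[("C", "A")])


def test_ols_exact_on_three_points():
    """Closed-form simple regression on 3 points is reproduced exactly."""
    design = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
    y = [1.0, 2.0, 2.0]
    res = ols_fit(y, design)  # textbook slope 0.5, intercept 7/6
    assert res.terms["x"]["estimate"] == pytest.approx(0.5)
    assert res.terms["Intercept"]["estimate"] == pytest.approx(7 / 6)


def test_ols_perfect_linear_fit():
    sogs = np.arange(10, dtype=float)
    design = pd.DataFrame({"SOGS": sogs})
    res = ols_fit(1.0 - 0.017 * sogs, design, outcome_name="beta")
    assert res.terms["SOGS"]["estimate"] == pytest.approx(-0.017)
    assert res.r_squared == pytest.approx(1.0)


def test_ols_rejects_collinear_design():
    design = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
    with pytest.raises(ValueError, match="collinear"):
        ols_fit([1.0, 2.0, 3.0, 4.0], design)


def test_ols_slope_recovery_is_unbiased(rng):
    """Mean estimate over seeded replicates sits on the generating slope."""
    n, true_slope, reps = 74, -0.017, 300
    estimates = []
    for _ in range(reps):
        sogs = np.clip(np.round(rng.normal(4.5, 4.0, n)), 0, 20)
        male = (rng.random(n) < 0.8).astype(float)
        age = rng.normal(39, 15, n)
        beta = 1.0 + true_slope * sogs + rng.normal(0, 0.1, n)
        design = pd.DataFrame({"SOGS": sogs, "Male": male, "Age": age})
        estimates.append(ols_fit(beta, design).terms["SOGS"]["estimate"])
    mc_err = np.std(estimates) / np.sqrt(reps)
    assert abs(np.mean(estimates) - true_slope) < 3 * mc_err


def test_pearson_formatting_and_df():
    x = np.linspace(0, 1, 74)
    y = 0.5 * x + np.sin(np.arange(74)) * 0.1
    rep = pearson_report(x, y)
    assert rep["df"] == 72
    assert rep["formatted"].startswith("r(72)=")


def test_pearson_perfect_and_null(rng):
    x = np.arange(10.0)
    assert pearson_report(x, 2 * x + 1)["r"] == pytest.approx(1.0)
    a, b = rng.standard_normal(1000), rng.standard_normal(1000)
    assert abs(pearson_report(a, b)["r"]) < 0.1
    with pytest.raises(ValueError):
        pearson_report(x, np.ones(10))
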