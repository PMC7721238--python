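"""Cohort statistics: t-tests, chi-square, ANCOVA, partial correlation."""

import numpy as np
import pandas as pd
import pytest

from scdprog import (
    GroupSummary,
    adjusted_group_compare,
    bonferroni_threshold,
    chi2_2x2,
    partial_correlation,
    t_test,
    t_test_from_summary,
    table1_report,
)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


def test_pooled_t_reproduces_drink_years_row():
    # stable group n=52 mean 5.54 sd 11.71; progressive n=24 mean 7.21 sd 16.54
    res = t_test_from_summary(GroupSummary(52, 5.54, 11.71, 24, 7.21, 16.54), "pooled")
    assert res.statistic == pytest.approx(-0.505, abs=5e-4)
    assert res.p == pytest.approx(0.615, abs=5e-3)
    assert res.df == 74


def test_identical_group_summaries_give_t_zero():
    res = t_test_from_summary(GroupSummary(10, 5.0, 2.0, 10, 5.0, 2.0), "pooled")
    assert res.statistic == 0.0
    assert res.p == 1.0


def test_pooled_equals_welch_for_balanced_equal_sd():
    s = GroupSummary(15, 3.0, 1.5, 15, 4.2, 1.5)
    pooled = t_test_from_summary(s, "pooled")
    welch = t_test_from_summary(s, "welch")
    assert pooled.statistic == pytest.approx(welch.statistic, rel=1e-12)
    assert pooled.df == pytest.approx(welch.df, rel=1e-9)


def test_zero_variance_both_groups_raises():
    with pytest.raises(ValueError, match="zero variance"):
        t_test_from_summary(GroupSummary(5, 1.0, 0.0, 5, 2.0, 0.0))


def test_auto_rule_gates_on_levene():
    rng = np.random.default_rng(0)
    x1 = rng.normal(0, 1, 80)
    x2 = rng.normal(0.3, 6, 80)  # grossly unequal variances
    res = t_test(x1, x2, variance_rule="auto")
    assert res.kind == "t_welch"
    res2 = t_test(x1, rng.normal(0.3, 1, 80), variance_rule="auto")
    assert res2.kind == "t_pooled"


def test_t_sign_flips_under_group_swap():
    rng = np.random.default_rng(1)
    x1, x2 = rng.normal(0, 1, 20), rng.normal(1, 1, 25)
    a = t_test(x1, x2, "pooled")
    b = t_test(x2, x1, "pooled")
    assert a.statistic == pytest.approx(-b.statistic)
    assert a.p == pytest.approx(b.p)


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

TABLE1_DICHOTOMOUS = [
    # (stable yes/no, progressive yes/no, printed chi2, expected kind)
    ("gender", (25, 27), (11, 13), 0.033, "chi2_pearson"),
    ("heart_disease", (16, 36), (8, 16), 0.050, "chi2_pearson"),
    ("stroke_baseline", (3, 49), (4, 20), 1.211, "chi2_yates"),
    ("surgery", (29, 21), (10, 14), 1.736, "chi2_pearson"),
    ("stroke_followup", (7, 45), (2, 22), 0.068, "chi2_yates"),
]


@pytest.mark.parametrize("name,stable,prog,printed,kind", TABLE1_DICHOTOMOUS)
def test_auto_correction_reproduces_printed_dichotomous_rows(name, stable, prog, printed, kind):
    table = [[stable[0], prog[0]], [stable[1], prog[1]]]
    res = chi2_2x2(table, correction="auto")
    assert res.statistic == pytest.approx(printed, abs=5e-4)
    assert res.kind == kind


def test_pearson_matches_brute_force_and_scipy():
    from scipy.stats import chi2_contingency

    rng = np.random.default_rng(3)
    for _ in range(20):
        O = rng.integers(1, 40, size=(2, 2)).astype(float)
        res = chi2_2x2(O, correction="pearson")
        E = np.outer(O.sum(1), O.sum(0)) / O.sum()
        assert res.statistic == pytest.approx(((O - E) ** 2 / E).sum(), rel=1e-12)
        assert res.statistic == pytest.approx(
            chi2_contingency(O, correction=False).statistic, rel=1e-10
        )


def test_proportional_rows_give_zero_chi2():
    res = chi2_2x2([[10, 20], [5, 10]], correction="pearson")
    assert res.statistic == 0.0
    assert res.p == 1.0


def test_chi2_zero_margin_raises():
    with pytest.raises(ValueError, match="margin"):
        chi2_2x2([[0, 0], [5, 10]])


def test_chi2_invariant_under_group_swap():
    a = chi2_2x2([[3, 4], [49, 20]], "auto")
    b = chi2_2x2([[4, 3], [20, 49]], "auto")
    assert a.statistic == pytest.approx(b.statistic)


# ---------------------------------------------------------------------------
# adjusted comparison
# ---------------------------------------------------------------------------


def test_adjusted_compare_orthogonal_covariates_match_unadjusted_f():
    rng = np.random.default_rng(4)
    n = 40
    group = np.array([0] * 20 + [1] * 20, dtype=float)
    cov = rng.normal(size=n)
    cov = cov - cov.mean()
    cov[:20] -= cov[:20].mean()  # orthogonalize to group
    cov[20:] -= cov[20:].mean()
    y = rng.normal(size=n) + 0.8 * group
    y = y - np.polyval(np.polyfit(cov, y, 1), cov) + y.mean()  # remove cov trend
    from scipy.stats import f_oneway

    res = adjusted_group_compare(y, group, cov)
    plain = f_oneway(y[group == 0], y[group == 1])
    assert res.statistic == pytest.approx(plain.statistic, rel=0.05)


def test_adjusted_compare_outcome_explained_by_covariates():
    rng = np.random.default_rng(5)
    n = 30
    group = rng.integers(0, 2, size=n).astype(float)
    cov = rng.normal(size=(n, 2))
    y = 2.0 + cov @ np.array([1.5, -0.7])  # exactly linear in covariates
    res = adjusted_group_compare(y, group, cov)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_adjusted_compare_detects_planted_moca_effect():
    detected = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        n = 76
        group = np.array([1] * 24 + [0] * 52, dtype=float)
        age = rng.normal(70, 7, n)
        edu = rng.normal(9, 3.5, n)
        moca = 24 - 0.05 * (age - 70) + 0.2 * (edu - 9) - 3.0 * group + rng.normal(0, 2, n)
        res = adjusted_group_compare(moca, group, np.column_stack([age, edu]))
        if res.p < 0.001:
            detected += 1
    assert detected >= 0.95 * n_seeds


def test_adjusted_compare_rank_deficiency_raises():
    with pytest.raises(ValueError, match="rank"):
        adjusted_group_compare(
            np.arange(10.0), np.repeat([0.0, 1.0], 5), np.repeat([0.0, 1.0], 5)
        )


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------


def test_partial_correlation_no_covariates_is_pearson():
    rng = np.random.default_rng(6)
    x, y = rng.normal(size=50), rng.normal(size=50)
    res = partial_correlation(x, y)
    assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)


def test_partial_correlation_perfect_dependence():
    rng = np.random.default_rng(7)
    x = rng.normal(size=20)
    cov = rng.normal(size=20)
    res = partial_correlation(x, x.copy(), cov)
    assert res.r == pytest.approx(1.0)


def test_partial_correlation_matches_precision_matrix_oracle():
    # 6-point constructed dataset; oracle inverts the full correlation matrix
    x = np.array([1.0, 2.0, 3.5, 2.2, 5.1, 4.0])
    y = np.array([0.8, 1.9, 2.2, 3.0, 4.6, 3.1])
    z = np.array([0.2, 0.5, 1.5, 0.9, 2.0, 1.8])
    R = np.corrcoef(np.vstack([x, y, z]))
    P = np.linalg.inv(R)
    oracle = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
    res = partial_correlation(x, y, z)
    assert res.r == pytest.approx(oracle, abs=1e-12)


def test_partial_correlation_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(8)
    n = 40
    cov = rng.normal(size=(n, 2))
    x = cov @ [0.5, -0.2] + rng.normal(size=n)
    y = cov @ [0.3, 0.4] + 0.5 * x + rng.normal(size=n)
    df = pd.DataFrame({"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1]})
    ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
    res = partial_correlation(x, y, cov)
    assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
    assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)


def test_partial_correlation_too_few_points_raises():
    with pytest.raises(ValueError, match="too few"):
        partial_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], np.ones((3, 2)))


# ---------------------------------------------------------------------------
# Bonferroni and the report
# ---------------------------------------------------------------------------


def test_bonferroni_printed_thresholds():
    assert bonferroni_threshold(0.05, 12) == pytest.approx(0.0042, abs=5e-5)
    assert bonferroni_threshold(0.1, 4) == 0.025
    assert bonferroni_threshold(0.05, 1) == 0.05


def test_bonferroni_zero_family_raises():
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


def test_table1_report_row_per_variable():
    rng = np.random.default_rng(9)
    n = 40
    labels = np.array([0] * 28 + [1] * 12)
    df = pd.DataFrame(
        {
            "age": rng.normal(70, 7, n),
            "moca": rng.normal(24, 4, n),
            "stroke": rng.integers(0, 2, n),
        }
    )
    report = table1_report(df, labels, adjusted={"moca": ["age"]})
    assert set(report["variable"]) == {"age", "moca", "stroke"}
    assert report.set_index("variable").loc["moca", "kind"] == "F_ancova"
    assert report.set_index("variable").loc["stroke", "type"] == "dichotomous"


def test_table1_report_identical_groups_all_nonsignificant():
    n = 30
    labels = np.array([0] * 20 + [1] * 10)
    base = np.concatenate([np.linspace(0, 1, 10)] * 3)
    df = pd.DataFrame({"v1": base, "v2": base * 2})
    report = table1_report(df, labels)
    # groups drawn from the same values: nothing should look significant
    assert (report["p"] > 0.2).all()
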