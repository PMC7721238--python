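"""Univariate and adjusted cohort statistics.

Implements the descriptive battery accompanying the prediction pipeline:
two-tailed independent-samples t-tests (from raw data or printed summary
statistics), 2x2 chi-square tests with an automatic continuity-correction
rule, covariate-adjusted group comparison of continuous outcomes, partial
correlation with residualization, and Bonferroni thresholds.

The chi-square ``auto`` rule applies the Yates correction iff any expected
cell count falls below 5, the conventional small-sample rule.  Statistic
kinds are always labelled explicitly because a publication-style table mixes
pooled-t, Welch-t, chi-square, and ANCOVA-F rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "StatTestResult",
    "PartialCorrelationResult",
    "t_test_from_summary",
    "t_test",
    "chi2_2x2",
    "adjusted_group_compare",
    "partial_correlation",
    "bonferroni_threshold",
    "table1_report",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group summary for a continuous variable (group 1 listed first)."""

    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n > 1 for a t-test")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("standard deviations must be nonnegative")


@dataclass(frozen=True)
class StatTestResult:
    statistic: float
    kind: str  # t_pooled | t_welch | chi2_pearson | chi2_yates | F_ancova
    df: float | tuple[float, float]
    p: float


@dataclass(frozen=True)
class PartialCorrelationResult:
    r: float
    p: float
    n: int
    n_covariates: int


def t_test_from_summary(summary: GroupSummary, variance_rule: str = "pooled") -> StatTestResult:
    """Two-tailed independent-samples t-test from group summary statistics.

    ``pooled`` uses the combined-variance estimator with n1+n2-2 degrees of
    freedom; ``welch`` uses per-group variances with Welch-Satterthwaite df.
    The statistic's sign follows group1 - group2.
    """
    if variance_rule not in ("pooled", "welch"):
        raise ValueError("variance_rule must be 'pooled' or 'welch' for summary input")
    if summary.sd1 == 0 and summary.sd2 == 0:
        raise ValueError("zero variance in both groups")
    res = sps.ttest_ind_from_stats(
        summary.mean1,
        summary.sd1,
        summary.n1,
        summary.mean2,
        summary.sd2,
        summary.n2,
        equal_var=(variance_rule == "pooled"),
    )
    if variance_rule == "pooled":
        df = summary.n1 + summary.n2 - 2
    else:
        v1, v2 = summary.sd1**2 / summary.n1, summary.sd2**2 / summary.n2
        df = (v1 + v2) ** 2 / (v1**2 / (summary.n1 - 1) + v2**2 / (summary.n2 - 1))
    return StatTestResult(
        statistic=float(res.statistic),
        kind=f"t_{variance_rule}",
        df=float(df),
        p=float(res.pvalue),
    )


def t_test(x1, x2, variance_rule: str = "auto", levene_alpha: float = 0.05) -> StatTestResult:
    """t-test on raw data; ``auto`` gates pooled vs Welch on Levene's test.

    The gate follows the common statistical-package convention: when
    Levene's test (mean-centered) rejects equal variances at
    ``levene_alpha``, the Welch statistic is reported.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if variance_rule == "auto":
        lev_p = sps.levene(x1, x2, center="mean").pvalue
        variance_rule = "welch" if lev_p < levene_alpha else "pooled"
    summary = GroupSummary(
        n1=len(x1),
        mean1=float(x1.mean()),
        sd1=float(x1.std(ddof=1)),
        n2=len(x2),
        mean2=float(x2.mean()),
        sd2=float(x2.std(ddof=1)),
    )
    return t_test_from_summary(summary, variance_rule)


def chi2_2x2(counts, correction: str = "auto") -> StatTestResult:
    """Chi-square test of a 2x2 table (rows = categories, columns = groups).

    ``pearson``: sum (O-E)^2 / E.  ``yates``: sum (max(|O-E| - 0.5, 0))^2 / E.
    ``auto`` selects Yates iff any expected cell is below 5.  df = 1.
    """
    O = np.asarray(counts, dtype=float)
    if O.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if (O < 0).any() or not np.allclose(O, np.round(O)):
        raise ValueError("counts must be nonnegative integers")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("2x2 table has a zero margin")
    E = np.outer(row, col) / O.sum()
    if correction == "auto":
        correction = "yates" if (E < 5).any() else "pearson"
    if correction == "pearson":
        stat = float(((O - E) ** 2 / E).sum())
    elif correction == "yates":
        stat = float((np.maximum(np.abs(O - E) - 0.5, 0.0) ** 2 / E).sum())
    else:
        raise ValueError("correction must be 'pearson', 'yates' or 'auto'")
    return StatTestResult(
        statistic=stat, kind=f"chi2_{correction}", df=1.0, p=float(sps.chi2.sf(stat, 1))
    )


def adjusted_group_compare(y, group, covariates) -> StatTestResult:
    """Group effect on a continuous outcome after covariate adjustment.

    Fits the linear model y ~ group + covariates (with intercept) and
    reports the group term's partial F statistic on (1, n - p) degrees of
    freedom (equal to the squared t of the group coefficient), i.e. the
    ANCOVA-style adjusted comparison.  If the covariates alone already
    explain the outcome exactly, the group effect is reported as F = 0.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != len(y):
        cov = cov.T
    X = sm.add_constant(np.column_stack([group, cov]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates)")
    full = sm.OLS(y, X).fit()
    reduced = sm.OLS(y, sm.add_constant(cov)).fit()
    df_resid = full.df_resid
    tss = float(np.sum((y - y.mean()) ** 2))
    if reduced.ssr <= 1e-12 * max(tss, 1.0):
        # covariates alone fit perfectly: nothing left for the group term
        return StatTestResult(statistic=0.0, kind="F_ancova", df=(1.0, float(df_resid)), p=1.0)
    F = float((reduced.ssr - full.ssr) / (full.ssr / df_resid))
    p = float(sps.f.sf(F, 1, df_resid))
    return StatTestResult(statistic=F, kind="F_ancova", df=(1.0, float(df_resid)), p=p)


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_correlation(x, y, covariates=None) -> PartialCorrelationResult:
    """Pearson correlation of x and y after regressing out covariates.

    Both vectors are residualized on the covariates plus an intercept; the
    p-value comes from the t transform with n - n_covariates - 2 degrees of
    freedom.  With no covariates this reduces to the plain Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        Z = np.ones((n, 1))
        n_cov = 0
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        n_cov = cov.shape[1]
        Z = np.column_stack([np.ones(n), cov])
    df = n - n_cov - 2
    if df < 1:
        raise ValueError("too few observations for the covariate count")
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("constant residuals; correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return PartialCorrelationResult(r=r, p=p, n=n, n_covariates=n_cov)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m for a family of m tests."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return alpha / m


def table1_report(
    df: pd.DataFrame,
    labels,
    continuous: Sequence[str] | None = None,
    dichotomous: Sequence[str] | None = None,
    adjusted: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Publication-style per-variable comparison of the two outcome groups.

    Continuous variables get a t-test (``auto`` variance rule, or ANCOVA-F
    if the variable is listed in ``adjusted`` with its covariate names);
    dichotomous variables get a chi-square with the ``auto`` correction
    rule.  Unlisted columns are classified dichotomous iff their values are
    all 0/1.  Group 1 of each comparison is the stable group.
    """
    labels = np.asarray(labels, dtype=int)
    stable = labels == 0
    prog = labels == 1
    adjusted = dict(adjusted or {})
    if continuous is None and dichotomous is None:
        dichotomous = [
            c for c in df.columns if np.isin(df[c].dropna().unique(), [0, 1]).all()
        ]
        continuous = [c for c in df.columns if c not in dichotomous]
    continuous = list(continuous or [])
    dichotomous = list(dichotomous or [])

    rows = []
    for var in continuous:
        v = df[var].to_numpy(dtype=float)
        if var in adjusted:
            cov = df[list(adjusted[var])].to_numpy(dtype=float)
            res = adjusted_group_compare(v, labels, cov)
        elif np.allclose(v[stable].var(), 0) and np.allclose(v[prog].var(), 0):
            res = StatTestResult(0.0, "t_pooled", float(len(v) - 2), 1.0)
        else:
            res = t_test(v[stable], v[prog], variance_rule="auto")
        rows.append(
            {
                "variable": var,
                "type": "continuous",
                "stable_mean": v[stable].mean(),
                "stable_sd": v[stable].std(ddof=1),
                "progressive_mean": v[prog].mean(),
                "progressive_sd": v[prog].std(ddof=1),
                "statistic": res.statistic,
                "kind": res.kind,
                "p": res.p,
            }
        )
    for var in dichotomous:
        v = df[var].to_numpy(dtype=float)
        table = np.array(
            [
                [np.sum(v[stable] == 1), np.sum(v[prog] == 1)],
                [np.sum(v[stable] == 0), np.sum(v[prog] == 0)],
            ]
        )
        if (table.sum(axis=1) == 0).any():
            res = StatTestResult(0.0, "chi2_pearson", 1.0, 1.0)
        else:
            res = chi2_2x2(table, correction="auto")
        rows.append(
            {
                "variable": var,
                "type": "dichotomous",
                "stable_yes": int(table[0, 0]),
                "stable_no": int(table[1, 0]),
                "progressive_yes": int(table[0, 1]),
                "progressive_no": int(table[1, 1]),
                "statistic": res.statistic,
                "kind": res.kind,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
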