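"""Conventional observational analyses: group comparisons and logistic ORs.

The baseline table compares normotensive and hypertensive groups with
independent t tests (continuous variables, ln scale where flagged) and
Pearson chi-square tests (categorical), plus covariate-adjusted p-values
from a linear model of the variable on the group indicator and age, sex and
BMI.  Descriptive means +/- SE are always shown on the original scale even
when the analysis ran on the ln scale.

Logistic odds ratios are reported per one-unit increase in the (possibly
ln-transformed) variable, crude and adjusted for age, sex and BMI.  A
variable that appears in its own covariate set gets an explicit
not-applicable marker, never a number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .mr import logistic_fit, ols_fit

__all__ = [
    "ComparisonRow", "ttest_independent", "chi2_test", "adjusted_compare",
    "logistic_or", "baseline_table", "NOT_APPLICABLE",
]

NOT_APPLICABLE = "—"


@dataclass
class ComparisonRow:
    variable: str
    mean_0: float
    se_0: float
    mean_1: float
    se_1: float
    p: float
    p_adjusted: float | str
    ln_flag: bool


def ttest_independent(values, group, welch: bool = False) -> tuple[float, float]:
    """Two-sided independent t test (equal-variance Student by default)."""
    values = np.asarray(values, float)
    group = np.asarray(group, float)
    ok = np.isfinite(values) & np.isfinite(group)
    a = values[ok & (group == 0)]
    b = values[ok & (group == 1)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def chi2_test(counts_2x2) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    obs = np.asarray(counts_2x2, float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("negative counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero margin")
    exp = np.outer(row, col) / n
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def adjusted_compare(cohort: Cohort, variable: str, group: str = "htn",
                     covars=("age", "sex", "bmi"),
                     ln_scale: bool = False):
    """Covariate-adjusted group comparison via a linear model.

    Fits ``variable ~ group + covars`` (on the ln scale if flagged) and
    returns (adjusted means per group at grand covariate means, adjusted p).
    A variable that is itself a covariate returns the not-applicable marker.
    """
    if variable in covars or variable == group:
        return None, NOT_APPLICABLE
    y = cohort.column(variable)
    if ln_scale:
        y = np.where(y > 0, np.log(np.where(y > 0, y, 1.0)), np.nan)
    g = cohort.column(group)
    C = np.column_stack([cohort.column(c) for c in covars])
    ok = np.isfinite(y) & np.isfinite(g) & np.isfinite(C).all(axis=1)
    X = np.column_stack([np.ones(int(ok.sum())), g[ok], C[ok]])
    fit = ols_fit(X, y[ok], names=["const", "group", *covars])
    p_adj = fit.p_named("group")
    cbar = C[ok].mean(axis=0)
    mean0 = float(fit.coef[0] + cbar @ fit.coef[2:])
    mean1 = float(mean0 + fit.coef[1])
    return (mean0, mean1), float(p_adj)


def logistic_or(cohort: Cohort, variable: str, outcome: str = "htn",
                covars=None, ln_scale: bool = False) -> tuple[float, tuple[float, float], float]:
    """Crude (covars=None) or adjusted logistic OR per one-unit increase.

    Returns ``(OR, (ci_low, ci_high), p)``; the not-applicable marker if the
    variable sits in its own covariate set.
    """
    if covars and variable in covars:
        return NOT_APPLICABLE, (NOT_APPLICABLE, NOT_APPLICABLE), NOT_APPLICABLE
    x = cohort.column(variable)
    if ln_scale:
        x = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan)
    h = cohort.column(outcome)
    covars = tuple(covars) if covars else ()
    C = (np.column_stack([cohort.column(c) for c in covars])
         if covars else np.empty((cohort.n, 0)))
    ok = np.isfinite(x) & np.isfinite(h)
    if C.size:
        ok &= np.isfinite(C).all(axis=1)
    X = np.column_stack([np.ones(int(ok.sum())), x[ok]] + ([C[ok]] if C.size else []))
    fit = logistic_fit(X, h[ok], names=["const", variable, *covars])
    or_val, lo, hi = fit.or_ci(variable)
    return or_val, (lo, hi), fit.p_named(variable)


def baseline_table(cohort: Cohort, variable_spec, group: str = "htn",
                   covars=("age", "sex", "bmi")) -> list[ComparisonRow]:
    """Per-variable descriptive comparison between outcome groups.

    ``variable_spec`` is a list of ``(name, ln_flag)`` pairs.  Descriptive
    means +/- SE are on the original scale; the t test runs on the ln scale
    where flagged; the adjusted p comes from :func:`adjusted_compare`.
    """
    g = cohort.column(group)
    rows: list[ComparisonRow] = []
    for name, ln_flag in variable_spec:
        y = cohort.column(name)
        ok = np.isfinite(y) & np.isfinite(g)
        a, b = y[ok & (g == 0)], y[ok & (g == 1)]
        y_an = (np.where(y > 0, np.log(np.where(y > 0, y, 1.0)), np.nan)
                if ln_flag else y)
        _, p = ttest_independent(y_an, g)
        _, p_adj = adjusted_compare(cohort, name, group, covars, ln_scale=ln_flag)
        rows.append(ComparisonRow(
            variable=name,
            mean_0=float(a.mean()), se_0=float(a.std(ddof=1) / np.sqrt(len(a))),
            mean_1=float(b.mean()), se_1=float(b.std(ddof=1) / np.sqrt(len(b))),
            p=float(p), p_adjusted=p_adj, ln_flag=ln_flag))
    return rows


def baseline_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variable": r.variable,
        "mean_normotensive": r.mean_0, "se_normotensive": r.se_0,
        "mean_hypertensive": r.mean_1, "se_hypertensive": r.se_1,
        "p": r.p, "p_adjusted": r.p_adjusted, "ln_scale": r.ln_flag,
    } for r in rows])
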