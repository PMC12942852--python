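"""Regression engines and the two-stage causal estimators.

The first stage regresses ln(TG) on an instrument (a single SNP dosage or a
weighted genetic risk score) plus covariates.  Three estimators consume it:

2SPS (two-stage predictor substitution)
    logistic regression of hypertension on the *fitted* ln(TG) plus
    covariates; the primary specification for the binary outcome.  With a
    nonlinear second stage this is an approximation.
2SRI (two-stage residual inclusion / control function)
    logistic regression of hypertension on the *observed* ln(TG), the
    first-stage residual, and covariates.
2SLS (two-stage least squares, linear probability model)
    the linear IV estimator with covariates as included instruments; it
    enables the Sargan overidentification test and the Wu-Hausman
    endogeneity test.

With a *linear* second stage, 2SPS, 2SRI and 2SLS coincide exactly for a
single endogenous regressor; that identity is exercised in the tests.

MR odds ratios are interpreted per one-unit increase in genetically
predicted ln(TG).  Weak instruments (first-stage F <= 10) produce a logged
warning, never a refusal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort

logger = logging.getLogger(__name__)

Z95 = 1.959964

__all__ = [
    "FitResult", "MREstimate", "DiagnosticsReport", "ols_fit", "logistic_fit",
    "first_stage", "two_stage_ps", "two_stage_ri", "two_sls", "sargan_test",
    "wu_hausman_test", "bootstrap_ci", "Z95",
]


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank-deficient; names the offending columns."""


class SeparationError(RuntimeError):
    """Logistic likelihood diverges (complete separation)."""


@dataclass
class FitResult:
    """A fitted linear or logistic model."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    stat: np.ndarray          # t (linear) or Wald z (logistic)
    p: np.ndarray
    cov: np.ndarray
    n: int
    df_residual: int
    fitted: np.ndarray
    residuals: np.ndarray
    r_squared: float | None = None
    log_likelihood: float | None = None
    extra: dict = field(default_factory=dict)

    def coef_named(self, name: str) -> float:
        return float(self.coef[self.names.index(name)])

    def se_named(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def p_named(self, name: str) -> float:
        return float(self.p[self.names.index(name)])

    def or_ci(self, name: str, z: float = Z95) -> tuple[float, float, float]:
        """(OR, CI low, CI high) for a logistic coefficient."""
        b, s = self.coef_named(name), self.se_named(name)
        return float(np.exp(b)), float(np.exp(b - z * s)), float(np.exp(b + z * s))


@dataclass
class MREstimate:
    """A method-tagged causal estimate with first-stage diagnostics."""

    method: str               # 2SPS | 2SRI | 2SLS
    instrument: str           # SNP id | GRS | crossfit-GRS | expanded-GRS
    estimate: float           # log-odds (2SPS/2SRI) or LPM slope (2SLS), per ln-unit
    se: float
    ci_low: float
    ci_high: float
    p: float
    first_stage_f: float
    first_stage_partial_r2: float
    first_stage_n: int
    n: int
    covariate_set: tuple[str, ...]
    se_method: str = "wald"
    or_value: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None

    @classmethod
    def from_logistic(cls, method, instrument, fit: FitResult, term, fs, covars,
                      se_method="wald"):
        b, s = fit.coef_named(term), fit.se_named(term)
        return cls(method=method, instrument=instrument, estimate=b, se=s,
                   ci_low=b - Z95 * s, ci_high=b + Z95 * s, p=fit.p_named(term),
                   first_stage_f=fs["F"], first_stage_partial_r2=fs["partial_r2"],
                   first_stage_n=fs["n"], n=fit.n, covariate_set=tuple(covars),
                   se_method=se_method, or_value=float(np.exp(b)),
                   or_ci_low=float(np.exp(b - Z95 * s)),
                   or_ci_high=float(np.exp(b + Z95 * s)))


@dataclass
class DiagnosticsReport:
    sargan_stat: float
    sargan_df: int
    sargan_p: float
    wu_hausman_stat: float
    wu_hausman_p: float

    def to_dict(self) -> dict:
        return {"sargan": {"stat": self.sargan_stat, "df": self.sargan_df,
                           "p": self.sargan_p},
                "wu_hausman": {"stat": self.wu_hausman_stat,
                               "p": self.wu_hausman_p}}


# ---------------------------------------------------------------------------
# Engines
# ---------------------------------------------------------------------------

def _design(design, names=None):
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(float), list(design.columns)
    X = np.asarray(design, float)
    if X.ndim == 1:
        X = X[:, None]
    names = names or [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full column rank
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise RankDeficientError(f"design is rank-deficient; collinear columns: {bad}")


def ols_fit(design, response, names=None) -> FitResult:
    """Least squares with classical (homoskedastic) standard errors.

    ``design`` must include any intercept column the caller wants.  Raises
    :class:`RankDeficientError` naming collinear columns, and refuses
    zero-degree-of-freedom fits.
    """
    X, names = _design(design, names)
    y = np.asarray(response, float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"no residual degrees of freedom (n={n}, parameters={k})")
    _check_rank(X, names)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    df = n - k
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan
    return FitResult(names=names, coef=coef, se=se, stat=t, p=p, cov=cov, n=n,
                     df_residual=df, fitted=fitted, residuals=resid, r_squared=r2)


def logistic_fit(design, response, names=None, maxiter: int = 100) -> FitResult:
    """Maximum-likelihood logistic regression (Wald inference).

    Backed by the statsmodels Newton solver; complete separation and
    non-convergence raise explicit errors.
    """
    X, names = _design(design, names)
    y = np.asarray(response, float)
    _check_rank(X, names)
    try:
        model = sm.Logit(y, X)
        res = model.fit(disp=0, maxiter=maxiter, method="newton", tol=1e-10)
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError) as e:
        raise SeparationError(f"logistic fit failed: {e}") from e
    if not res.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit did not converge "
                              f"in {maxiter} iterations")
    coef = np.asarray(res.params, float)
    if np.abs(coef).max() > 50:
        raise SeparationError("diverging coefficients suggest complete separation")
    cov = np.asarray(res.cov_params(), float)
    se = np.sqrt(np.diag(cov))
    z = coef / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    fitted = np.asarray(res.predict(), float)
    return FitResult(names=names, coef=coef, se=se, stat=z, p=p, cov=cov,
                     n=len(y), df_residual=len(y) - X.shape[1], fitted=fitted,
                     residuals=y - fitted, log_likelihood=float(res.llf))


# ---------------------------------------------------------------------------
# First stage
# ---------------------------------------------------------------------------

def _covar_matrix(cohort: Cohort, covars) -> np.ndarray:
    return (np.column_stack([cohort.column(c) for c in covars])
            if covars else np.empty((cohort.n, 0)))


def first_stage(cohort: Cohort, instrument, covars=("age", "sex", "bmi"),
                exposure: str = "ln_tg", instrument_name: str = "iv") -> FitResult:
    """Linear regression of the exposure on the instrument plus covariates.

    Attaches ``F`` (= t^2 for the single instrument term), ``partial_r2``
    (= t^2 / (t^2 + df_residual)), and a complete-case mask ``rows`` in
    ``extra``.  F <= 10 logs a weak-instrument warning but still returns.
    """
    z = np.asarray(instrument, float)
    y = cohort.column(exposure)
    C = _covar_matrix(cohort, covars)
    ok = np.isfinite(z) & np.isfinite(y)
    if C.size:
        ok &= np.isfinite(C).all(axis=1)
    X = np.column_stack([np.ones(ok.sum()), z[ok]] + ([C[ok]] if C.size else []))
    fit = ols_fit(X, y[ok], names=["const", instrument_name, *covars])
    t = fit.stat[1]
    F = float(t * t)
    fit.extra["F"] = F
    fit.extra["partial_r2"] = float(t * t / (t * t + fit.df_residual))
    fit.extra["rows"] = ok
    fit.extra["n"] = fit.n
    if F <= 10:
        logger.warning("weak instrument %s: first-stage F = %.2f <= 10",
                       instrument_name, F)
    return fit


def _first_stage_summary(fit: FitResult) -> dict:
    return {"F": fit.extra["F"], "partial_r2": fit.extra["partial_r2"], "n": fit.n}


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def two_stage_ps(cohort: Cohort, instrument, covars=("age", "sex", "bmi"),
                 exposure: str = "ln_tg", outcome: str = "htn",
                 label: str = "iv") -> MREstimate:
    """2SPS: logistic regression of the outcome on genetically predicted exposure."""
    fs = first_stage(cohort, instrument, covars, exposure, label)
    ok = fs.extra["rows"].copy()
    h = cohort.column(outcome)
    ok &= np.isfinite(h)
    # refit first stage on rows where outcome is present, if any were lost
    if ok.sum() != fs.n:
        sub = Cohort(data=cohort.data.loc[ok].reset_index(drop=True))
        return two_stage_ps(sub, np.asarray(instrument, float)[ok], covars,
                            exposure, outcome, label)
    xhat = np.full(cohort.n, np.nan)
    xhat[ok] = fs.fitted
    C = _covar_matrix(cohort, covars)
    X = np.column_stack([np.ones(int(ok.sum())), xhat[ok]] + ([C[ok]] if C.size else []))
    fit = logistic_fit(X, h[ok], names=["const", "pred_exposure", *covars])
    return MREstimate.from_logistic("2SPS", label, fit, "pred_exposure",
                                    _first_stage_summary(fs), covars)


def two_stage_ri(cohort: Cohort, instrument, covars=("age", "sex", "bmi"),
                 exposure: str = "ln_tg", outcome: str = "htn",
                 label: str = "iv") -> MREstimate:
    """2SRI: logistic regression on observed exposure plus first-stage residual."""
    fs = first_stage(cohort, instrument, covars, exposure, label)
    ok = fs.extra["rows"].copy()
    h = cohort.column(outcome)
    ok &= np.isfinite(h)
    if ok.sum() != fs.n:
        sub = Cohort(data=cohort.data.loc[ok].reset_index(drop=True))
        return two_stage_ri(sub, np.asarray(instrument, float)[ok], covars,
                            exposure, outcome, label)
    x = cohort.column(exposure)
    C = _covar_matrix(cohort, covars)
    X = np.column_stack([np.ones(int(ok.sum())), x[ok], fs.residuals]
                        + ([C[ok]] if C.size else []))
    fit = logistic_fit(X, h[ok], names=["const", "exposure", "fs_residual", *covars])
    est = MREstimate.from_logistic("2SRI", label, fit, "exposure",
                                   _first_stage_summary(fs), covars)
    return est


def two_sls(cohort: Cohort, instruments, covars=("age", "sex", "bmi"),
            exposure: str = "ln_tg", outcome: str = "htn",
            robust: bool = False, label: str = "iv") -> MREstimate:
    """2SLS linear probability model with covariates as included instruments.

    ``instruments`` is an (n, k) array (or list of columns) of excluded
    instruments.  Classical IV standard errors by default;
    heteroskedasticity-robust (HC0) behind ``robust=True``.  The fitted
    object for diagnostics is attached on the returned estimate as
    ``_diag`` (residuals, instrument matrix, rows).
    """
    if isinstance(instruments, (list, tuple)):
        Zx = np.column_stack([np.asarray(z, float) for z in instruments])
    else:
        Zx = np.asarray(instruments, float)
    if Zx.ndim == 1:
        Zx = Zx[:, None]
    x = cohort.column(exposure)
    y = cohort.column(outcome)
    C = _covar_matrix(cohort, covars)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(Zx).all(axis=1)
    if C.size:
        ok &= np.isfinite(C).all(axis=1)
    n = int(ok.sum())
    ones = np.ones(n)
    W = np.column_stack([ones] + ([C[ok]] if C.size else []))      # included
    Z = np.column_stack([W, Zx[ok]])                                # all instruments
    X = np.column_stack([ones, x[ok]] + ([C[ok]] if C.size else []))  # regressors
    names = ["const", "exposure", *covars]
    _check_rank(Z, [f"z{j}" for j in range(Z.shape[1])])
    _check_rank(X, names)
    PZ_X = Z @ np.linalg.lstsq(Z, X, rcond=None)[0]     # projection of X on Z
    # X_hat'X = X_hat'X_hat, so the 2SLS solution is the least-squares fit
    # of y on the projected regressors (QR route, numerically stable)
    beta = np.linalg.lstsq(PZ_X, y[ok], rcond=None)[0]
    resid = y[ok] - X @ beta
    df = n - X.shape[1]
    bread = np.linalg.inv(PZ_X.T @ PZ_X)
    if robust:
        meat = (PZ_X * resid[:, None] ** 2).T @ PZ_X
        cov = bread @ meat @ bread
    else:
        sigma2 = float(resid @ resid) / df
        cov = sigma2 * bread
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)

    # first-stage strength of the (joint) instruments for the exposure
    fs_fit = ols_fit(Z, x[ok], names=[f"z{j}" for j in range(Z.shape[1])])
    fs_null = ols_fit(W, x[ok], names=[f"w{j}" for j in range(W.shape[1])])
    k_ex = Zx.shape[1]
    rss1 = float(fs_fit.residuals @ fs_fit.residuals)
    rss0 = float(fs_null.residuals @ fs_null.residuals)
    df_fs = n - Z.shape[1]
    F = ((rss0 - rss1) / k_ex) / (rss1 / df_fs) if rss1 > 0 else np.inf
    partial_r2 = (rss0 - rss1) / rss0 if rss0 > 0 else np.nan
    if F <= 10:
        logger.warning("weak instruments: joint first-stage F = %.2f <= 10", F)

    b = float(beta[1])
    s = float(se[1])
    est = MREstimate(method="2SLS", instrument=label, estimate=b, se=s,
                     ci_low=b - Z95 * s, ci_high=b + Z95 * s, p=float(p[1]),
                     first_stage_f=float(F), first_stage_partial_r2=float(partial_r2),
                     first_stage_n=n, n=n, covariate_set=tuple(covars),
                     se_method="robust" if robust else "wald")
    est._diag = {"residuals": resid, "Z": Z, "W": W, "X": X, "rows": ok,
                 "n": n, "k_excluded": k_ex, "y": y[ok], "x": x[ok]}
    return est


def sargan_test(two_sls_result: MREstimate) -> tuple[float, int, float]:
    """Sargan overidentification test: n * R^2 of IV residuals on all instruments.

    Requires at least two excluded instruments for the single endogenous
    exposure (df = #instruments - 1); just-identified models raise.
    """
    d = getattr(two_sls_result, "_diag", None)
    if d is None:
        raise ValueError("two_sls_result lacks diagnostic state; use two_sls()")
    df = d["k_excluded"] - 1
    if df < 1:
        raise ValueError("just-identified model: df = 0, Sargan test undefined")
    aux = ols_fit(d["Z"], d["residuals"],
                  names=[f"z{j}" for j in range(d["Z"].shape[1])])
    stat = d["n"] * aux.r_squared
    p = float(stats.chi2.sf(stat, df))
    return float(stat), int(df), p


def wu_hausman_test(cohort: Cohort, instruments, covars=("age", "sex", "bmi"),
                    exposure: str = "ln_tg", outcome: str = "htn") -> tuple[float, float]:
    """Wu-Hausman endogeneity test via the augmented (control-function) regression.

    Regress the outcome on exposure, the joint first-stage residual, and
    covariates; the F statistic (= t^2) on the residual term tests exposure
    exogeneity under a linear outcome model.
    """
    Zx = np.asarray(instruments, float)
    if Zx.ndim == 1:
        Zx = Zx[:, None]
    x = cohort.column(exposure)
    y = cohort.column(outcome)
    C = _covar_matrix(cohort, covars)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(Zx).all(axis=1)
    if C.size:
        ok &= np.isfinite(C).all(axis=1)
    n = int(ok.sum())
    ones = np.ones(n)
    Z = np.column_stack([ones] + ([C[ok]] if C.size else []) + [Zx[ok]])
    fs = ols_fit(Z, x[ok], names=[f"z{j}" for j in range(Z.shape[1])])
    if float(fs.residuals @ fs.residuals) <= 1e-12 * n:
        raise ValueError("first-stage residual is identically zero; "
                         "Wu-Hausman test undefined")
    X = np.column_stack([ones, x[ok], fs.residuals] + ([C[ok]] if C.size else []))
    aug = ols_fit(X, y[ok], names=["const", "exposure", "fs_residual", *covars])
    t = aug.stat[aug.names.index("fs_residual")]
    stat = float(t * t)
    p = float(stats.f.sf(stat, 1, aug.df_residual))
    return stat, p


def bootstrap_ci(estimator, cohort: Cohort, instrument, B: int = 1000,
                 seed: int = 0, alpha: float = 0.05, **kwargs) -> tuple[float, float]:
    """Nonparametric case-resampling percentile CI re-running both stages.

    ``estimator`` is one of the two-stage functions taking
    (cohort, instrument, ...) and returning an :class:`MREstimate`.  Fails if
    more than 5% of replicates error (e.g. separation in a resample).
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = np.random.default_rng(seed)
    inst = np.asarray(instrument, float)
    n = cohort.n
    estimates, failures = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        data = cohort.data.iloc[idx].reset_index(drop=True)
        data["sample_id"] = [f"b{i}" for i in range(n)]
        try:
            est = estimator(Cohort(data=data), inst[idx], **kwargs)
            estimates.append(est.estimate)
        except Exception:
            failures += 1
    if failures > 0.05 * B:
        raise RuntimeError(f"estimator failed in {failures}/{B} bootstrap replicates")
    lo, hi = np.percentile(estimates, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
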