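"""Instrument screening, strength arithmetic, and genetic risk scores.

Candidate SNPs from the suggestive scan pass through prespecified
instrumental-variable safeguards, each recorded in an audit trail:

``strength``
    first-stage F > 10 (F = t^2 for a single instrument term; partial
    R^2 = t^2 / (t^2 + df), df = n - #covariates - 2 counting the
    intercept).
``independence``
    no association with the major covariates age, sex (logistic) and BMI
    at alpha = 0.05.
``direct_outcome``
    no covariate-adjusted association with hypertension at alpha = 0.05; a
    *significant opposite-signed* association relative to the TG-increasing
    orientation is recorded separately as ``direction_inconsistent``.

Retained instruments are oriented so the counted allele raises ln(TG)
(first-stage beta > 0).  The weighted GRS sums risk-allele dosages weighted
by the first-stage coefficients; a K-fold, outcome-stratified cross-fitting
variant estimates each individual's weights on the other folds to remove
in-sample weight optimism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import Cohort, GenotypeMatrix
from .mr import SeparationError, first_stage, logistic_fit, ols_fit

__all__ = [
    "AuditRow", "InstrumentVariant", "InstrumentSet", "GRSVector",
    "instrument_strength", "partial_r2_from_f", "check_covariate_independence",
    "check_outcome_direct", "negative_control_scan", "select_instruments",
    "build_grs", "crossfit_grs", "expanded_grs", "NoValidInstrumentsError",
]


class NoValidInstrumentsError(RuntimeError):
    """Raised when every candidate fails the prespecified screening rules."""


@dataclass
class AuditRow:
    variant_id: str
    check: str
    statistic: float
    p: float
    passed: bool
    reason: str = ""


@dataclass
class InstrumentVariant:
    variant_id: str
    counted_allele: str
    weight: float                 # ln-units per risk allele, > 0 after orientation
    beta: float
    se: float
    f_stat: float
    partial_r2: float
    n_used: int
    flipped: bool = False         # True if orientation reversed the counted allele
    sensitivity_only: bool = False


@dataclass
class InstrumentSet:
    variants: list[InstrumentVariant]
    audit: list[AuditRow]
    covariate_set: tuple[str, ...]

    @property
    def ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(a) for a in self.audit])

    def table(self) -> pd.DataFrame:
        """Instrument report with the field's customary rounding (3 dp for
        beta/R^2, 1 dp for F)."""
        rows = [{
            "id": v.variant_id, "counted_allele": v.counted_allele,
            "n": v.n_used, "beta": round(v.beta, 3), "se": round(v.se, 3),
            "F": round(v.f_stat, 1), "partial_r2": round(v.partial_r2, 3),
        } for v in self.variants]
        return pd.DataFrame(rows)


@dataclass
class GRSVector:
    """Per-individual weighted risk-allele score (complete-case)."""

    scores: np.ndarray            # NaN where any instrument genotype missing
    n_complete: int
    weight_provenance: str        # in-sample | out-of-fold
    fold_id: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Strength arithmetic
# ---------------------------------------------------------------------------

def partial_r2_from_f(f_stat: float, df: int) -> float:
    """partial R^2 = F / (F + df), the single-parameter identity t^2 = F."""
    return f_stat / (f_stat + df)


def instrument_strength(dosage, cohort: Cohort, covars=("age", "sex", "bmi"),
                        exposure: str = "ln_tg"):
    """First-stage strength of one instrument: (beta, se, t, F, partial_r2, n).

    F = t^2 and partial R^2 = t^2/(t^2 + df) with df = n - (#covars + 2);
    for an unadjusted model pass ``covars=()`` (df = n - 2).
    """
    fit = first_stage(cohort, dosage, covars, exposure, "dosage")
    t = float(fit.stat[1])
    return (float(fit.coef[1]), float(fit.se[1]), t, fit.extra["F"],
            fit.extra["partial_r2"], fit.n)


# ---------------------------------------------------------------------------
# Screening checks
# ---------------------------------------------------------------------------

def check_covariate_independence(dosage, cohort: Cohort,
                                 covars=("age", "sex", "bmi"),
                                 alpha: float = 0.05,
                                 variant_id: str = "?") -> list[AuditRow]:
    """Regress each major covariate on dosage (sex via logistic); fail if p < alpha."""
    z = np.asarray(dosage, float)
    rows: list[AuditRow] = []
    finite = z[np.isfinite(z)]
    if finite.size == 0 or finite.std() == 0:
        return [AuditRow(variant_id, "independence", np.nan, np.nan, False,
                         "degenerate")]
    for covar in covars:
        y = cohort.column(covar)
        ok = np.isfinite(z) & np.isfinite(y)
        X = np.column_stack([np.ones(int(ok.sum())), z[ok]])
        binary = set(np.unique(y[ok])) <= {0.0, 1.0}
        try:
            fit = (logistic_fit if binary else ols_fit)(X, y[ok], names=["const", "dosage"])
            p = fit.p_named("dosage")
            stat = float(fit.stat[1])
        except (SeparationError, ValueError):
            rows.append(AuditRow(variant_id, f"independence:{covar}", np.nan,
                                 np.nan, False, "unstable"))
            continue
        rows.append(AuditRow(variant_id, f"independence:{covar}", stat, p,
                             p >= alpha, "" if p >= alpha else "covariate_associated"))
    return rows


def check_outcome_direct(dosage, cohort: Cohort, covars=("age", "sex", "bmi"),
                         alpha: float = 0.05, variant_id: str = "?",
                         tg_increasing_sign: float = 1.0,
                         outcome: str = "htn") -> AuditRow:
    """Covariate-adjusted logistic screen for a direct outcome association.

    Fails with ``direct_association`` if p < alpha, or with
    ``direction_inconsistent`` if additionally the coefficient's sign
    opposes the TG-increasing orientation.  A non-convergent fit rejects the
    candidate as ``unstable``.
    """
    z = np.asarray(dosage, float)
    h = cohort.column(outcome)
    C = (np.column_stack([cohort.column(c) for c in covars])
         if covars else np.empty((cohort.n, 0)))
    ok = np.isfinite(z) & np.isfinite(h)
    if C.size:
        ok &= np.isfinite(C).all(axis=1)
    finite = z[ok]
    if finite.size == 0 or finite.std() == 0:
        return AuditRow(variant_id, "direct_outcome", np.nan, np.nan, False,
                        "degenerate")
    X = np.column_stack([np.ones(int(ok.sum())), z[ok]] + ([C[ok]] if C.size else []))
    try:
        fit = logistic_fit(X, h[ok], names=["const", "dosage", *covars])
    except SeparationError:
        return AuditRow(variant_id, "direct_outcome", np.nan, np.nan, False,
                        "unstable")
    p = fit.p_named("dosage")
    coef = fit.coef_named("dosage")
    if p < alpha:
        reason = ("direction_inconsistent"
                  if np.sign(coef) != np.sign(tg_increasing_sign)
                  else "direct_association")
        return AuditRow(variant_id, "direct_outcome", float(fit.stat[1]), p,
                        False, reason)
    return AuditRow(variant_id, "direct_outcome", float(fit.stat[1]), p, True)


def negative_control_scan(instrument_set: InstrumentSet, cohort: Cohort,
                          genotypes: GenotypeMatrix, biomarkers,
                          covars=("age", "sex", "bmi")) -> pd.DataFrame:
    """Reporting-only covariate-adjusted regressions of biomarkers on instruments.

    Nominal p-values, no multiplicity correction; never used for selection.
    """
    rows = []
    for v in instrument_set.variants:
        z = genotypes.column(v.variant_id)
        for biom in biomarkers:
            y = cohort.column(biom)
            C = (np.column_stack([cohort.column(c) for c in covars])
                 if covars else np.empty((cohort.n, 0)))
            ok = np.isfinite(z) & np.isfinite(y)
            if C.size:
                ok &= np.isfinite(C).all(axis=1)
            X = np.column_stack([np.ones(int(ok.sum())), z[ok]]
                                + ([C[ok]] if C.size else []))
            fit = ols_fit(X, y[ok], names=["const", "dosage", *covars])
            rows.append({"instrument": v.variant_id, "biomarker": biom,
                         "beta": fit.coef_named("dosage"),
                         "p": fit.p_named("dosage"), "n": fit.n})
    return pd.DataFrame(rows, columns=["instrument", "biomarker", "beta", "p", "n"])


# ---------------------------------------------------------------------------
# Selection and scores
# ---------------------------------------------------------------------------

@dataclass
class ScreeningRules:
    f_min: float = 10.0
    screen_alpha: float = 0.05
    covariate_set: tuple[str, ...] = ("age", "sex", "bmi")


def _oriented(dosage: np.ndarray, beta: float) -> tuple[np.ndarray, bool]:
    """Flip 0/1/2 dosage to count the TG-increasing allele (beta > 0)."""
    if beta >= 0:
        return dosage, False
    return 2.0 - dosage, True


def _flip_allele(variants: pd.DataFrame, vid: str) -> str:
    row = variants.loc[variants["id"] == vid].iloc[0]
    counted = row["counted_allele"]
    other = row["ref_allele"] if counted == row["alt_allele"] else row["alt_allele"]
    return str(other)


def select_instruments(candidate_ids, cohort: Cohort, genotypes: GenotypeMatrix,
                       rules: ScreeningRules | None = None,
                       exposure: str = "ln_tg") -> InstrumentSet:
    """Apply the prespecified screens to scan candidates; emit a full audit.

    Retained variants pass strength (F > f_min), covariate independence, and
    the direct-outcome screen; their dosages are oriented so the first-stage
    beta (hence the GRS weight) is positive.  Raises
    :class:`NoValidInstrumentsError` when nothing survives.
    """
    rules = rules or ScreeningRules()
    audit: list[AuditRow] = []
    retained: list[InstrumentVariant] = []
    for vid in candidate_ids:
        z = genotypes.column(vid)
        finite = z[np.isfinite(z)]
        if finite.size == 0 or finite.std() == 0:
            audit.append(AuditRow(vid, "strength", np.nan, np.nan, False, "degenerate"))
            continue
        beta, se, t, F, pr2, n = instrument_strength(z, cohort, rules.covariate_set,
                                                     exposure)
        strong = F > rules.f_min
        audit.append(AuditRow(vid, "strength", F, np.nan, strong,
                              "" if strong else "weak"))
        z_or, flipped = _oriented(z, beta)
        indep_rows = check_covariate_independence(z, cohort, rules.covariate_set,
                                                  rules.screen_alpha, vid)
        audit.extend(indep_rows)
        direct = check_outcome_direct(z_or, cohort, rules.covariate_set,
                                      rules.screen_alpha, vid)
        audit.append(direct)
        if not (strong and all(r.passed for r in indep_rows) and direct.passed):
            continue
        beta_or = abs(beta)
        allele = (genotypes.variants.loc[genotypes.variants["id"] == vid,
                                         "counted_allele"].iloc[0])
        if flipped:
            allele = _flip_allele(genotypes.variants, vid)
        retained.append(InstrumentVariant(
            variant_id=vid, counted_allele=str(allele), weight=beta_or,
            beta=beta_or, se=se, f_stat=F, partial_r2=pr2, n_used=n,
            flipped=flipped))
    if not retained:
        raise NoValidInstrumentsError(
            "no candidates passed the prespecified instrument screens")
    return InstrumentSet(variants=retained, audit=audit,
                         covariate_set=tuple(rules.covariate_set))


def _oriented_dosage(genotypes: GenotypeMatrix, v: InstrumentVariant) -> np.ndarray:
    z = genotypes.column(v.variant_id)
    return 2.0 - z if v.flipped else z


def build_grs(genotypes: GenotypeMatrix, instrument_set: InstrumentSet) -> GRSVector:
    """score_i = sum_j weight_j * oriented dosage_ij, complete-case."""
    cols = np.column_stack([_oriented_dosage(genotypes, v)
                            for v in instrument_set.variants])
    weights = np.array([v.weight for v in instrument_set.variants])
    complete = np.isfinite(cols).all(axis=1)
    scores = np.full(genotypes.n_samples, np.nan)
    scores[complete] = cols[complete] @ weights
    return GRSVector(scores=scores, n_complete=int(complete.sum()),
                     weight_provenance="in-sample")


def _fold_weights(cols: np.ndarray, cohort: Cohort, rows: np.ndarray,
                  covars, exposure: str) -> np.ndarray:
    """Per-SNP first-stage coefficients estimated on the given rows."""
    sub = Cohort(data=cohort.data.loc[rows].reset_index(drop=True))
    weights = np.empty(cols.shape[1])
    for j in range(cols.shape[1]):
        fit = first_stage(sub, cols[rows, j], covars, exposure, f"snp{j}")
        weights[j] = fit.coef[1]
    return weights


def crossfit_grs(genotypes: GenotypeMatrix, cohort: Cohort, candidate_ids,
                 K: int = 10, seed: int = 0, covars=("age", "sex", "bmi"),
                 exposure: str = "ln_tg", outcome: str = "htn") -> GRSVector:
    """Out-of-fold weighted GRS with outcome-stratified random folds.

    For each fold k the per-SNP weights come from the first-stage regressions
    on the other K-1 folds; fold-k individuals are scored with those weights.
    Oriented per fold so each weight is applied to the allele it was
    estimated for (weights may be negative out-of-fold; they are applied
    as estimated).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    n = cohort.n
    # at least 4 rows per fold on average, so every training split can
    # support the first-stage fit in both outcome strata
    if n < 4 * K:
        raise ValueError(f"too few individuals ({n}) for K={K} folds")
    cols = np.column_stack([genotypes.column(v) for v in candidate_ids])
    h = cohort.column(outcome)
    usable = np.isfinite(h) & np.isfinite(cols).all(axis=1)
    y = cohort.column(exposure)
    usable &= np.isfinite(y)
    for c in covars:
        usable &= np.isfinite(cohort.column(c))
    idx = np.flatnonzero(usable)
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed & 0x7FFFFFFF)
    scores = np.full(n, np.nan)
    fold_id = np.full(n, -1)
    for k, (train_loc, test_loc) in enumerate(skf.split(idx, h[idx])):
        train_rows = np.zeros(n, dtype=bool)
        train_rows[idx[train_loc]] = True
        if train_rows.sum() <= len(covars) + 2:
            raise ValueError(f"fold {k}: too few rows to fit the first stage")
        w = _fold_weights(cols, cohort, train_rows, covars, exposure)
        test_rows = idx[test_loc]
        scores[test_rows] = cols[test_rows] @ w
        fold_id[test_rows] = k
    return GRSVector(scores=scores, n_complete=int(np.isfinite(scores).sum()),
                     weight_provenance="out-of-fold", fold_id=fold_id)


def crossfit_heldout_test(cohort: Cohort, cf: GRSVector,
                          covars=("age", "sex", "bmi"),
                          exposure: str = "ln_tg") -> list[tuple[int, float, float]]:
    """Score-exposure association evaluated fold by fold.

    Each fold's score was weighted without that fold's data, so the
    fold-level t test of exposure on score (plus covariates) is correctly
    sized even when the candidate SNPs have no real effect.  Fold statistics
    are *not* independent of one another (their weights share training
    data), so they are returned per fold rather than pooled into a single
    test.  Returns (fold, t, p) triples.
    """
    if cf.fold_id is None:
        raise ValueError("GRSVector has no fold assignment; use crossfit_grs")
    out = []
    for k in sorted(set(cf.fold_id[cf.fold_id >= 0])):
        rows = cf.fold_id == k
        sub = Cohort(data=cohort.data.loc[rows].reset_index(drop=True))
        fit = first_stage(sub, cf.scores[rows], covars, exposure, "score")
        out.append((int(k), float(fit.stat[1]), float(fit.p[1])))
    return out


def expanded_grs(genotypes: GenotypeMatrix, cohort: Cohort,
                 instrument_set: InstrumentSet, extra_variant: str,
                 rules: ScreeningRules | None = None,
                 exposure: str = "ln_tg") -> InstrumentSet:
    """Sensitivity-only instrument set adding one variant past the outcome screen.

    The extra variant must still satisfy the strength rule; it is flagged
    ``sensitivity_only`` in the audit and the variant list.  An extra variant
    collinear with an existing instrument is rejected.
    """
    rules = rules or ScreeningRules()
    z = genotypes.column(extra_variant)
    for v in instrument_set.variants:
        existing = genotypes.column(v.variant_id)
        ok = np.isfinite(z) & np.isfinite(existing)
        if ok.sum() > 2 and np.std(z[ok]) > 0 and np.std(existing[ok]) > 0:
            r = np.corrcoef(z[ok], existing[ok])[0, 1]
            if abs(r) > 0.999:
                raise ValueError(f"extra variant {extra_variant} is collinear "
                                 f"with instrument {v.variant_id}")
    beta, se, t, F, pr2, n = instrument_strength(z, cohort, rules.covariate_set,
                                                 exposure)
    if F <= rules.f_min:
        raise ValueError(f"extra variant {extra_variant} fails the strength rule "
                         f"(F = {F:.2f})")
    _, flipped = _oriented(z, beta)
    allele = (genotypes.variants.loc[genotypes.variants["id"] == extra_variant,
                                     "counted_allele"].iloc[0])
    if flipped:
        allele = _flip_allele(genotypes.variants, extra_variant)
    extra = InstrumentVariant(variant_id=extra_variant, counted_allele=str(allele),
                              weight=abs(beta), beta=abs(beta), se=se, f_stat=F,
                              partial_r2=pr2, n_used=n, flipped=flipped,
                              sensitivity_only=True)
    audit = list(instrument_set.audit)
    audit.append(AuditRow(extra_variant, "strength", F, np.nan, True,
                          "sensitivity_only"))
    return InstrumentSet(variants=[*instrument_set.variants, extra],
                         audit=audit, covariate_set=instrument_set.covariate_set)
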