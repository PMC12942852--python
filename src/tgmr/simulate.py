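"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: genotypes
drawn under Hardy-Weinberg equilibrium, a log-normal triglyceride exposure
with small per-allele SNP effects, age/sex/BMI covariates, an unobserved
confounder U, and a binary hypertension outcome whose intercept is calibrated
by Monte-Carlo root-finding to hit a target prevalence.

Named scenario presets:

``null``
    no causal TG effect, no confounding — everything is noise.
``causal``
    TG raises hypertension risk (log-odds ln 2 per ln-unit by default) with
    confounding active; a valid-instrument setting.
``confounded_null``
    no causal TG effect but U raises both TG and hypertension, so the crude
    observational odds ratio is inflated while the MR estimand is null.
``pleiotropic``
    causal setting plus one instrument with a direct (non-TG-mediated)
    log-odds effect on hypertension — an instrument-validity violation.

The generator is a pure function of its config and seed.  The confounder and
all true parameters are returned in a :class:`TruthRecord` that is never
written into the analysis-facing tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import Cohort, GenotypeMatrix, classify_hypertension

__all__ = [
    "SimulationConfig", "TruthRecord", "simulate_genotypes", "simulate_covariates",
    "simulate_exposure", "calibrate_intercept", "simulate_outcome",
    "simulate_linear_outcome", "simulate_cohort", "inject_missingness", "preset",
]

_SCENARIOS = ("null", "causal", "confounded_null", "pleiotropic")


@dataclass
class SimulationConfig:
    """Full generative recipe for one synthetic cohort draw.

    Defaults mirror the study conditions: n = 2159 individuals, three
    instrument SNPs with MAFs (0.05, 0.15, 0.20) and per-allele effects on
    ln(TG) of (0.145, 0.069, 0.072) ln-units, residual exposure SD sized so
    the combined instrument R^2 is ~0.02, and a 25.2% hypertension
    prevalence target.
    """

    n: int = 2159
    instrument_mafs: tuple[float, ...] = (0.05, 0.15, 0.20)
    instrument_betas: tuple[float, ...] = (0.145, 0.069, 0.072)
    n_null_snps: int = 500
    null_maf_range: tuple[float, float] = (0.05, 0.5)
    # exposure model (ln-units)
    alpha0: float = 4.7
    gamma_age: float = 0.008
    gamma_sex: float = -0.18
    gamma_bmi: float = 0.035
    gamma_u: float = 0.2
    exposure_sd: float = 0.3938
    # outcome model (log-odds)
    theta_tg: float = 0.0
    theta_age: float = 0.06
    theta_sex: float = -0.40
    theta_bmi: float = 0.15
    theta_u: float = 0.5
    target_prevalence: float = 544 / 2159
    pleiotropy_delta: float = 0.0
    pleiotropic_index: int = 2
    missing_rate: float = 0.004
    seed: int = 0
    scenario: str = "causal"

    def __post_init__(self) -> None:
        mafs = np.asarray(self.instrument_mafs, float)
        if np.any((mafs <= 0) | (mafs > 0.5)):
            raise ValueError("instrument MAFs must lie in (0, 0.5]")
        if len(self.instrument_mafs) != len(self.instrument_betas):
            raise ValueError("instrument_mafs and instrument_betas differ in length")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class TruthRecord:
    """Ground truth withheld from the analysis-facing tables."""

    theta_tg: float
    theta0: float
    instrument_betas: tuple[float, ...]
    realized_prevalence: float
    confounder: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "theta_tg": self.theta_tg,
            "theta0": self.theta0,
            "instrument_betas": list(self.instrument_betas),
            "realized_prevalence": self.realized_prevalence,
        }


def preset(scenario: str, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` for a named scenario."""
    base: dict = {"scenario": scenario}
    if scenario == "null":
        base.update(theta_tg=0.0, gamma_u=0.0, theta_u=0.0)
    elif scenario == "causal":
        base.update(theta_tg=float(np.log(2.0)))
    elif scenario == "confounded_null":
        base.update(theta_tg=0.0)
    elif scenario == "pleiotropic":
        base.update(theta_tg=float(np.log(2.0)), pleiotropy_delta=0.15)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    base.update(overrides)
    return SimulationConfig(**base)


def _child_seed(seed: int, label: str) -> int:
    """Stable sub-stream seed below 2^31."""
    h = seed & 0x7FFFFFFF
    for ch in label:
        h = (h * 31 + ord(ch)) % 0x80000000
    return h


def simulate_genotypes(n: int, mafs, seed: int, id_prefix: str = "snp",
                       chrom_start: int = 1) -> GenotypeMatrix:
    """Draw dosages ~ Binomial(2, maf) independently per variant under HWE."""
    mafs = np.asarray(mafs, float)
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("MAFs must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, mafs[None, :], size=(n, len(mafs))).astype(float)
    m = len(mafs)
    variants = pd.DataFrame({
        "id": [f"{id_prefix}{j}" for j in range(m)],
        "chrom": [str(chrom_start + (j % 22)) for j in range(m)],
        "pos": (np.arange(m) // 22 + 1) * 1000 + np.arange(m) % 22,
        "ref_allele": "A",
        "alt_allele": "G",
        "counted_allele": "G",
    })
    # distinct positions within chromosome: spread by index
    variants["pos"] = 10_000 + np.arange(m) * 5_000
    sample_ids = np.array([f"S{i:06d}" for i in range(n)])
    return GenotypeMatrix(dosages=dosages, variants=variants, sample_ids=sample_ids)


def simulate_covariates(n: int, seed: int) -> pd.DataFrame:
    """Age ~ N(50,10) truncated to [20,86]; 40% male; BMI ~ N(24+0.02(age-50), 3)."""
    rng = np.random.default_rng(seed)
    age = rng.normal(50.0, 10.0, size=n)
    while True:
        out = (age < 20) | (age > 86)
        if not out.any():
            break
        age[out] = rng.normal(50.0, 10.0, size=out.sum())
    sex = (rng.random(n) >= 0.40).astype(float)  # 1 = female (60%)
    bmi = rng.normal(24.0 + 0.02 * (age - 50.0), 3.0)
    u = rng.normal(0.0, 1.0, size=n)
    return pd.DataFrame({"age": age, "sex": sex, "bmi": bmi, "_u": u})


def simulate_exposure(genotypes: GenotypeMatrix, covariates: pd.DataFrame,
                      config: SimulationConfig, seed: int) -> np.ndarray:
    """ln(TG) = a0 + sum_j beta_j g_j + covariate terms + gamma_u U + eps."""
    g = genotypes.dosages[:, : len(config.instrument_betas)]
    if g.shape[0] != len(covariates):
        raise ValueError("genotypes and covariates have different lengths")
    rng = np.random.default_rng(seed)
    betas = np.asarray(config.instrument_betas, float)
    age_c = covariates["age"].to_numpy() - 50.0
    bmi_c = covariates["bmi"].to_numpy() - 24.0
    lin = (config.alpha0
           + np.nan_to_num(g) @ betas
           + config.gamma_age * age_c
           + config.gamma_sex * covariates["sex"].to_numpy()
           + config.gamma_bmi * bmi_c
           + config.gamma_u * covariates["_u"].to_numpy())
    return lin + rng.normal(0.0, config.exposure_sd, size=len(covariates))


def _outcome_linpred(theta0, ln_tg, genotypes, covariates, config):
    age_c = covariates["age"].to_numpy() - 50.0
    bmi_c = covariates["bmi"].to_numpy() - 24.0
    lp = (theta0
          + config.theta_tg * ln_tg
          + config.theta_age * age_c
          + config.theta_sex * covariates["sex"].to_numpy()
          + config.theta_bmi * bmi_c
          + config.theta_u * covariates["_u"].to_numpy())
    if config.pleiotropy_delta != 0.0:
        lp = lp + config.pleiotropy_delta * np.nan_to_num(
            genotypes.dosages[:, config.pleiotropic_index])
    return lp


_CALIBRATION_N = 100_000
_CALIBRATION_SEED = 20_260_214 & 0x7FFFFFFF


def calibrate_intercept(config: SimulationConfig, seed: int | None = None,
                        n: int = _CALIBRATION_N, tol: float = 1e-4) -> float:
    """Find theta0 so the mean outcome probability hits the target prevalence.

    Root-finding on a fixed large Monte-Carlo draw; the mean of
    expit(theta0 + Z) is strictly increasing in theta0, so bisection on an
    expanding bracket always converges.  With every effect at zero this
    reduces to logit(target_prevalence) exactly.
    """
    seed = _CALIBRATION_SEED if seed is None else seed
    geno = simulate_genotypes(n, config.instrument_mafs, _child_seed(seed, "geno"))
    cov = simulate_covariates(n, _child_seed(seed, "cov"))
    ln_tg = simulate_exposure(geno, cov, config, _child_seed(seed, "expo"))
    z = _outcome_linpred(0.0, ln_tg, geno, cov, config)

    def gap(theta0: float) -> float:
        return float(expit(theta0 + z).mean() - config.target_prevalence)

    lo, hi = float(logit(config.target_prevalence) - z.mean()), 0.0
    lo, hi = lo - 5.0, lo + 5.0
    for _ in range(40):
        if gap(lo) < 0 < gap(hi):
            break
        lo -= 5.0
        hi += 5.0
    else:
        raise RuntimeError("intercept calibration failed to bracket the root")
    return float(brentq(gap, lo, hi, xtol=tol))


def simulate_outcome(ln_tg, genotypes: GenotypeMatrix, covariates: pd.DataFrame,
                     config: SimulationConfig, theta0: float, seed: int) -> np.ndarray:
    """Draw htn_i ~ Bernoulli(expit(linear predictor))."""
    ln_tg = np.asarray(ln_tg, float)
    if len(ln_tg) != len(covariates):
        raise ValueError("ln_tg and covariates have different lengths")
    rng = np.random.default_rng(seed)
    p = expit(_outcome_linpred(theta0, ln_tg, genotypes, covariates, config))
    return (rng.random(len(p)) < p).astype(float)


def simulate_linear_outcome(ln_tg, genotypes: GenotypeMatrix, covariates: pd.DataFrame,
                            config: SimulationConfig, seed: int,
                            noise_sd: float = 1.0) -> np.ndarray:
    """Continuous analogue of the outcome model (for linear-IV experiments)."""
    rng = np.random.default_rng(seed)
    lp = _outcome_linpred(0.0, np.asarray(ln_tg, float), genotypes, covariates, config)
    return lp + rng.normal(0.0, noise_sd, size=len(covariates))


def inject_missingness(genotypes: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set entries missing independently at the given rate."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must lie in [0, 1)")
    if rate == 0.0:
        return genotypes
    rng = np.random.default_rng(seed)
    mask = rng.random(genotypes.dosages.shape) < rate
    dosages = genotypes.dosages.copy()
    dosages[mask] = np.nan
    return GenotypeMatrix(dosages=dosages, variants=genotypes.variants.copy(),
                          sample_ids=genotypes.sample_ids)


def simulate_cohort(config: SimulationConfig,
                    theta0: float | None = None) -> tuple[Cohort, GenotypeMatrix, TruthRecord]:
    """End-to-end cohort draw ready for the analysis pipeline.

    The instrument SNPs come first in the genotype matrix (on chromosomes 5,
    22, 8, echoing the loci they stand in for), followed by ``n_null_snps``
    exposure-independent SNPs with MAFs uniform over ``null_maf_range``.
    Blood-pressure columns are generated so that the hypertension flag
    classified from them reproduces the simulated outcome; the confounder U
    never enters the phenotype table.
    """
    seed = config.seed
    rng = np.random.default_rng(_child_seed(seed, "misc"))
    n = config.n

    inst = simulate_genotypes(n, config.instrument_mafs, _child_seed(seed, "inst"))
    inst_meta = inst.variants.copy()
    inst_meta["id"] = [f"iv{j}" for j in range(len(config.instrument_mafs))]
    inst_meta["chrom"] = (["5", "22", "8"] + [str(c) for c in range(9, 23)])[: len(inst_meta)]
    inst_meta["pos"] = 50_000 + np.arange(len(inst_meta)) * 10_000

    if config.n_null_snps > 0:
        null_mafs = np.random.default_rng(_child_seed(seed, "nullmaf")).uniform(
            *config.null_maf_range, size=config.n_null_snps)
        nulls = simulate_genotypes(n, null_mafs, _child_seed(seed, "null"),
                                   id_prefix="null")
        dosages = np.hstack([inst.dosages, nulls.dosages])
        variants = pd.concat([inst_meta, nulls.variants], ignore_index=True)
    else:
        dosages = inst.dosages
        variants = inst_meta
    genotypes = GenotypeMatrix(dosages=dosages, variants=variants,
                               sample_ids=inst.sample_ids)

    cov = simulate_covariates(n, _child_seed(seed, "cov"))
    ln_tg = simulate_exposure(genotypes, cov, config, _child_seed(seed, "expo"))
    if theta0 is None:
        theta0 = calibrate_intercept(config)
    htn = simulate_outcome(ln_tg, genotypes, cov, config, theta0,
                           _child_seed(seed, "outcome"))

    # Blood pressure consistent with the classification rule: hypertensives
    # get SBP >= 140 or medication; normotensives stay below both cutoffs.
    sbp = rng.normal(118.0, 10.0, size=n).clip(90.0, 139.0)
    dbp = rng.normal(74.0, 7.0, size=n).clip(55.0, 89.0)
    on_med = np.zeros(n)
    hyp = htn > 0
    n_hyp = int(hyp.sum())
    if n_hyp:
        treated = rng.random(n_hyp) < 0.5
        sbp_h = rng.normal(150.0, 8.0, size=n_hyp).clip(140.0, 200.0)
        dbp_h = rng.normal(92.0, 6.0, size=n_hyp).clip(90.0, 120.0)
        sbp[hyp] = np.where(treated, rng.normal(128.0, 8.0, size=n_hyp).clip(95.0, 139.0), sbp_h)
        dbp[hyp] = np.where(treated, rng.normal(80.0, 6.0, size=n_hyp).clip(60.0, 89.0), dbp_h)
        on_med[hyp] = treated.astype(float)

    tg = np.exp(ln_tg)
    glucose = np.exp(rng.normal(np.log(96.0) + 0.001 * (cov["age"] - 50.0), 0.10))
    insulin = np.exp(rng.normal(np.log(9.0) + 0.03 * (cov["bmi"] - 24.0), 0.35))
    hdl = np.exp(rng.normal(np.log(52.0) - 0.15 * (ln_tg - ln_tg.mean()), 0.18))
    ldl = rng.normal(120.0, 25.0, size=n).clip(40.0, None)
    apoa1 = rng.normal(156.0, 20.0, size=n).clip(60.0, None)
    apob = rng.normal(104.0, 22.0, size=n).clip(30.0, None)
    hscrp = np.exp(rng.normal(np.log(0.8), 0.9, size=n))

    data = pd.DataFrame({
        "sample_id": genotypes.sample_ids,
        "age": cov["age"].to_numpy(),
        "sex": cov["sex"].to_numpy(),
        "bmi": cov["bmi"].to_numpy(),
        "sbp": sbp,
        "dbp": dbp,
        "on_htn_med": on_med,
        "tg": tg,
        "glucose": glucose,
        "insulin": insulin,
        "hdl_c": hdl,
        "ldl_c": ldl,
        "apoa1": apoa1,
        "apob": apob,
        "hs_crp": hscrp,
        "ln_tg": ln_tg,
        "htn": classify_hypertension(sbp, dbp, on_med),
    })
    cohort = Cohort(data=data)
    assert np.array_equal(cohort.data["htn"].to_numpy(), htn)

    if config.missing_rate > 0:
        genotypes = inject_missingness(genotypes, config.missing_rate,
                                       _child_seed(seed, "miss"))

    truth = TruthRecord(
        theta_tg=config.theta_tg,
        theta0=theta0,
        instrument_betas=tuple(config.instrument_betas),
        realized_prevalence=float(htn.mean()),
        confounder=cov["_u"].to_numpy(),
    )
    return cohort, genotypes, truth
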