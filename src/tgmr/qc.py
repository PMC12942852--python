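"""Genotype quality control, LD pruning, and the additive exposure scan.

The QC pipeline applies, in order: sample call-rate filter (>= 0.90), marker
call-rate filter (>= 0.95), minor-allele-frequency filter (>= 0.01), and an
exact Hardy-Weinberg equilibrium test (p >= 0.001).  LD pruning
(sliding 250-variant window, step 50, pairwise r^2 <= 0.5, per chromosome)
is applied only during instrument selection, not to the association scan.

The scan fits, per SNP, a complete-case linear model of the (ln-scale)
exposure on dosage plus covariates (age and sex by default) and reports
beta, SE, t, p, MAF and HWE p; candidates are SNPs below the suggestive
threshold p < 1e-5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import Cohort, GenotypeMatrix

__all__ = [
    "QCReport", "VariantStats", "call_rate_filter", "maf", "hwe_exact_p",
    "hwe_chi2_p", "qc_pipeline", "ld_prune", "additive_scan", "suggestive_hits",
    "QCThresholds",
]


@dataclass
class QCThresholds:
    sample_call_rate: float = 0.90
    marker_call_rate: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 0.001


@dataclass
class QCReport:
    """Per-filter removal counts and the thresholds that produced them."""

    thresholds: dict = field(default_factory=dict)
    samples_in: int = 0
    samples_removed_call_rate: int = 0
    markers_in: int = 0
    markers_removed_call_rate: int = 0
    markers_removed_maf: int = 0
    markers_removed_hwe: int = 0
    markers_removed_pruning: int = 0

    @property
    def samples_out(self) -> int:
        return self.samples_in - self.samples_removed_call_rate

    @property
    def markers_out(self) -> int:
        return (self.markers_in - self.markers_removed_call_rate
                - self.markers_removed_maf - self.markers_removed_hwe
                - self.markers_removed_pruning)

    def to_dict(self) -> dict:
        return {
            "thresholds": dict(self.thresholds),
            "samples": {"in": self.samples_in,
                        "removed_call_rate": self.samples_removed_call_rate,
                        "out": self.samples_out},
            "markers": {"in": self.markers_in,
                        "removed_call_rate": self.markers_removed_call_rate,
                        "removed_maf": self.markers_removed_maf,
                        "removed_hwe": self.markers_removed_hwe,
                        "removed_pruning": self.markers_removed_pruning,
                        "out": self.markers_out},
        }


@dataclass
class VariantStats:
    """Per-SNP additive-scan result."""

    variant_id: str
    n_used: int
    beta: float
    se: float
    t: float
    p: float
    maf: float
    hwe_p: float
    chrom: str = "0"
    pos: int = 0

    @property
    def defined(self) -> bool:
        return np.isfinite(self.beta) and np.isfinite(self.se)


def call_rate_filter(genotypes: GenotypeMatrix,
                     sample_min: float = 0.90,
                     marker_min: float = 0.95) -> tuple[GenotypeMatrix, QCReport]:
    """Remove low-call-rate samples first, then low-call-rate markers."""
    report = QCReport(thresholds={"sample_call_rate": sample_min,
                                  "marker_call_rate": marker_min},
                      samples_in=genotypes.n_samples, markers_in=genotypes.n_variants)
    obs = np.isfinite(genotypes.dosages)
    sample_rate = obs.mean(axis=1) if genotypes.n_variants else np.ones(genotypes.n_samples)
    keep_s = sample_rate >= sample_min
    report.samples_removed_call_rate = int((~keep_s).sum())
    gm = genotypes.subset_samples(keep_s)
    obs = np.isfinite(gm.dosages)
    marker_rate = obs.mean(axis=0) if gm.n_samples else np.ones(gm.n_variants)
    keep_m = marker_rate >= marker_min
    report.markers_removed_call_rate = int((~keep_m).sum())
    return gm.subset_variants(keep_m), report


def maf(dosage_column) -> float:
    """Minor allele frequency: min(f, 1-f), f = sum(dosage) / (2 * n_nonmissing)."""
    x = np.asarray(dosage_column, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("all-missing dosage column")
    f = x.sum() / (2.0 * x.size)
    return float(min(f, 1.0 - f))


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    P-value is the sum of probabilities, conditional on the observed allele
    counts, of all heterozygote counts whose probability does not exceed that
    of the observed count (the standard exact HWE formulation).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype column")
    n_a = n_Aa + 2 * n_aa          # minor-allele count (relabel if needed)
    if n_a > n:                    # ensure n_a is the rarer allele count
        n_a = 2 * n - n_a
    # possible heterozygote counts share the parity of n_a
    het_min = n_a % 2
    hets = np.arange(het_min, n_a + 1, 2)
    # log P(het) up to a constant: conditional distribution
    #   P(h) ∝ n_a! (2n-n_a)! / ( ((n_a-h)/2)! h! ((2n-n_a-h)/2)! ) * 2^h
    from scipy.special import gammaln
    rare_hom = (n_a - hets) // 2
    com_hom = n - rare_hom - hets
    logp = (hets * np.log(2.0)
            - gammaln(rare_hom + 1) - gammaln(hets + 1) - gammaln(com_hom + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed_het = n_Aa
    idx = np.flatnonzero(hets == observed_het)
    if idx.size == 0:
        raise ValueError("heterozygote count inconsistent with allele count")
    p_obs = probs[idx[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_chi2_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Chi-square (1 df) Hardy-Weinberg test — available behind a flag."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype column")
    p = (2 * n_AA + n_Aa) / (2.0 * n)
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_AA, n_Aa, n_aa], float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
    return float(stats.chi2.sf(terms.sum(), df=1))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    x = col[np.isfinite(col)]
    return int((x == 0).sum()), int((x == 1).sum()), int((x == 2).sum())


def hwe_p_column(col: np.ndarray, exact: bool = True) -> float:
    n0, n1, n2 = _genotype_counts(np.asarray(col, float))
    test = hwe_exact_p if exact else hwe_chi2_p
    return test(n0, n1, n2)


def qc_pipeline(genotypes: GenotypeMatrix,
                thresholds: QCThresholds | None = None,
                exact_hwe: bool = True) -> tuple[GenotypeMatrix, QCReport]:
    """Sample call rate -> marker call rate -> MAF -> HWE, with a report."""
    th = thresholds or QCThresholds()
    gm, report = call_rate_filter(genotypes, th.sample_call_rate, th.marker_call_rate)
    report.thresholds.update({"maf_min": th.maf_min, "hwe_p_min": th.hwe_p_min,
                              "hwe_test": "exact" if exact_hwe else "chi2"})
    mafs = np.array([maf(gm.dosages[:, j]) for j in range(gm.n_variants)])
    keep = mafs >= th.maf_min
    report.markers_removed_maf = int((~keep).sum())
    gm = gm.subset_variants(keep)
    hwe_ps = np.array([hwe_p_column(gm.dosages[:, j], exact=exact_hwe)
                       for j in range(gm.n_variants)])
    keep = hwe_ps >= th.hwe_p_min
    report.markers_removed_hwe = int((~keep).sum())
    return gm.subset_variants(keep), report


def sort_variants(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Return a copy with variants sorted by (chromosome, position, id)."""
    key = sorted(range(genotypes.n_variants),
                 key=lambda j: (str(genotypes.variants["chrom"].iloc[j]),
                                int(genotypes.variants["pos"].iloc[j]),
                                str(genotypes.variants["id"].iloc[j])))
    return genotypes.subset_variants(np.asarray(key))


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return 0.0
    x, y = a[ok], b[ok]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(genotypes: GenotypeMatrix, window: int = 250, step: int = 50,
             r2_max: float = 0.5) -> tuple[GenotypeMatrix, QCReport]:
    """Greedy windowed LD pruning per chromosome.

    Within each ``window``-variant window, each pair with dosage r^2 above
    ``r2_max`` loses its later member (by position, ties by id); the window
    slides by ``step`` variants.  Requires variants sorted by (chrom, pos).
    """
    variants = genotypes.variants
    order_key = list(zip(variants["chrom"], variants["pos"], variants["id"]))
    if order_key != sorted(order_key):
        raise ValueError("variants must be sorted by (chromosome, position)")
    removed = np.zeros(genotypes.n_variants, dtype=bool)
    for chrom in variants["chrom"].unique():
        idx = np.flatnonzero((variants["chrom"] == chrom).to_numpy())
        start = 0
        while True:
            win = idx[start:start + window]
            if win.size >= 2:
                active = [j for j in win if not removed[j]]
                for a_pos in range(len(active)):
                    ja = active[a_pos]
                    if removed[ja]:
                        continue
                    for jb in active[a_pos + 1:]:
                        if removed[jb]:
                            continue
                        if _pairwise_r2(genotypes.dosages[:, ja],
                                        genotypes.dosages[:, jb]) > r2_max:
                            removed[jb] = True  # later variant dropped
            if start + window >= idx.size:
                break
            start += step
    report = QCReport(thresholds={"window": window, "step": step, "r2_max": r2_max},
                      samples_in=genotypes.n_samples, markers_in=genotypes.n_variants,
                      markers_removed_pruning=int(removed.sum()))
    return genotypes.subset_variants(~removed), report


def _scan_one(y: np.ndarray, g: np.ndarray, covars: np.ndarray) -> tuple:
    """OLS of y on [1, g, covars], complete-case; returns beta, se, t, p, n."""
    ok = np.isfinite(y) & np.isfinite(g)
    if covars.size:
        ok &= np.isfinite(covars).all(axis=1)
    yy, gg = y[ok], g[ok]
    n = int(ok.sum())
    X = np.column_stack([np.ones(n), gg] + ([covars[ok]] if covars.size else []))
    p_params = X.shape[1]
    if n <= p_params or gg.std() == 0:
        return np.nan, np.nan, np.nan, np.nan, n
    coef, _, rank, _ = np.linalg.lstsq(X, yy, rcond=None)
    if rank < p_params:
        return np.nan, np.nan, np.nan, np.nan, n
    resid = yy - X @ coef
    df = n - p_params
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, se, t, float(p), n


def additive_scan(genotypes: GenotypeMatrix, cohort: Cohort,
                  exposure: str = "ln_tg",
                  covars: tuple[str, ...] = ("age", "sex")) -> list[VariantStats]:
    """Per-SNP additive linear scan of the exposure, adjusted for covariates.

    Constant-dosage columns yield NaN statistics (flagged ``defined=False``)
    rather than being silently dropped.
    """
    y = cohort.column(exposure)
    C = (np.column_stack([cohort.column(c) for c in covars])
         if covars else np.empty((cohort.n, 0)))
    out: list[VariantStats] = []
    for j in range(genotypes.n_variants):
        g = genotypes.dosages[:, j]
        beta, se, t, p, n = _scan_one(y, g, C)
        finite = g[np.isfinite(g)]
        v_maf = maf(g) if finite.size else np.nan
        v_hwe = hwe_p_column(g) if finite.size else np.nan
        meta = genotypes.variants.iloc[j]
        out.append(VariantStats(variant_id=str(meta["id"]), n_used=n, beta=beta,
                                se=se, t=t, p=p, maf=v_maf, hwe_p=v_hwe,
                                chrom=str(meta["chrom"]), pos=int(meta["pos"])))
    return out


def suggestive_hits(scan: list[VariantStats], alpha: float = 1e-5) -> list[str]:
    """Variant ids with p below the suggestive threshold, sorted by p."""
    hits = [(s.p, s.variant_id) for s in scan if np.isfinite(s.p) and s.p < alpha]
    return [vid for _, vid in sorted(hits)]
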