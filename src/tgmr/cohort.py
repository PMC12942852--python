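"""Phenotype and genotype containers, file I/O, and derived clinical variables.

The analysis operates on two aligned tables: a per-individual phenotype table
(age, sex, BMI, blood pressure, medication use, and serum biomarkers) and an
additive genotype dosage matrix (0/1/2 counts of a *counted* allele per
variant, with explicit missingness).  Derived variables follow standard
clinical definitions: hypertension is SBP >= 140 mmHg, DBP >= 90 mmHg, or
current antihypertensive medication; skewed biomarkers are analysed on the
natural-log scale; insulin resistance is summarised by HOMA-IR,
(fasting glucose [mmol/L] x fasting insulin [uIU/mL]) / 22.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: mg/dL per mmol/L for glucose (molar mass of glucose 180.16 g/mol).
GLUCOSE_MG_PER_MMOL = 18.016

#: Missing-value sentinel used in all delimited text interfaces.
NA_SENTINEL = "NA"

_RAW_LEADING = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]

REQUIRED_PHENOTYPES = ("sample_id", "age", "sex", "bmi", "sbp", "dbp", "on_htn_med")


class CohortError(ValueError):
    """Raised for malformed phenotype/genotype inputs."""


@dataclass
class PhenotypeSpec:
    """Column mapping and coding declarations for a phenotype table.

    ``columns`` maps canonical names (``sample_id``, ``age``, ``sex``, ``bmi``,
    ``sbp``, ``dbp``, ``on_htn_med`` plus any biomarker) to the file's header
    names.  ``sex_coding`` maps raw sex codes to 0 (reference = male) / 1
    (female).  ``na_values`` are treated as missing.
    """

    columns: dict[str, str] = field(default_factory=dict)
    sex_coding: dict[str, int] = field(default_factory=lambda: {"M": 0, "F": 1})
    na_values: tuple[str, ...] = (NA_SENTINEL, "")
    true_values: tuple[str, ...] = ("1", "True", "true", "Y", "yes")

    def __post_init__(self) -> None:
        mapped = list(self.columns.values())
        dups = {c for c in mapped if mapped.count(c) > 1}
        if dups:
            raise CohortError(f"columns mapped more than once: {sorted(dups)}")

    @classmethod
    def default(cls, biomarkers: tuple[str, ...] = ()) -> "PhenotypeSpec":
        cols = {name: name for name in REQUIRED_PHENOTYPES}
        cols.update({b: b for b in biomarkers})
        return cls(columns=cols)


@dataclass
class Cohort:
    """A per-individual phenotype table with derived analysis columns.

    ``data`` holds one row per individual, indexed by position, with a
    ``sample_id`` column of unique strings.  Biomarker columns are on the
    original measurement scale; derived columns (``ln_*``, ``homa_ir``,
    ``htn``) are added by the functions in this module.
    """

    data: pd.DataFrame
    ln_missing_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "sample_id" not in self.data.columns:
            raise CohortError("cohort table lacks a sample_id column")
        ids = self.data["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise CohortError(f"duplicate sample_id: {dup!r}")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data["sample_id"].to_numpy()

    @property
    def n(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


@dataclass
class GenotypeMatrix:
    """N x M additive dosage matrix with per-variant metadata.

    Dosages are floats in {0, 1, 2} with NaN marking missing calls.
    ``variants`` carries one row per column: id, chrom, pos (1-based),
    ref_allele, alt_allele and counted_allele (the allele the dosage counts).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.dosages.ndim != 2:
            raise CohortError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise CohortError("sample_ids do not match dosage rows")
        if len(self.variants) != m:
            raise CohortError("variant metadata does not match dosage columns")
        if self.variants["id"].duplicated().any():
            raise CohortError("variant ids are not unique")
        vals = self.dosages[np.isfinite(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise CohortError(f"dosage outside {{0,1,2,NA}}: {bad!r}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy()

    def column(self, variant_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.variant_ids == variant_id)
        if idx.size == 0:
            raise KeyError(f"variant {variant_id!r} not in genotype matrix")
        return self.dosages[:, idx[0]]

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            variants=self.variants.iloc[keep].reset_index(drop=True),
            sample_ids=self.sample_ids,
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            dosages=self.dosages[keep, :],
            variants=self.variants,
            sample_ids=self.sample_ids[keep],
        )


# ---------------------------------------------------------------------------
# Derived variables
# ---------------------------------------------------------------------------

def classify_hypertension(sbp, dbp, on_med):
    """Hypertension flag: SBP >= 140, DBP >= 90, or antihypertensive use.

    Vectorised; any missing input yields a missing (NaN) output so the row is
    excluded by downstream complete-case filters rather than misclassified.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    med = np.asarray(on_med, dtype=float)
    out = ((sbp >= 140.0) | (dbp >= 90.0) | (med > 0)).astype(float)
    out = np.where(np.isnan(sbp) | np.isnan(dbp) | np.isnan(med), np.nan, out)
    return out


def derive_ln(cohort: Cohort, column: str) -> Cohort:
    """Add ``ln_<column>`` (natural log); nonpositive values become missing.

    The count of nonpositive-to-missing conversions is recorded in
    ``cohort.ln_missing_counts`` and logged.
    """
    if column not in cohort.data.columns:
        raise CohortError(f"no such column: {column!r}")
    x = cohort.data[column].to_numpy(dtype=float)
    bad = np.isfinite(x) & (x <= 0)
    out = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan)
    data = cohort.data.copy()
    data[f"ln_{column}"] = out
    counts = dict(cohort.ln_missing_counts)
    counts[column] = counts.get(column, 0) + int(bad.sum())
    if bad.any():
        logger.info("derive_ln(%s): %d nonpositive values set to missing", column, bad.sum())
    return Cohort(data=data, ln_missing_counts=counts)


def derive_homa_ir(glucose_mg_dl, insulin_uIU_ml):
    """HOMA-IR = (glucose [mmol/L] * insulin [uIU/mL]) / 22.5.

    Glucose is supplied in mg/dL and converted by dividing by 18.016.
    """
    g = np.asarray(glucose_mg_dl, dtype=float)
    i = np.asarray(insulin_uIU_ml, dtype=float)
    if np.any(g[np.isfinite(g)] < 0) or np.any(i[np.isfinite(i)] < 0):
        raise CohortError("negative glucose or insulin")
    return (g / GLUCOSE_MG_PER_MMOL) * i / 22.5


def derive_homa_ir_column(cohort: Cohort, glucose="glucose", insulin="insulin") -> Cohort:
    data = cohort.data.copy()
    data["homa_ir"] = derive_homa_ir(data[glucose].to_numpy(float), data[insulin].to_numpy(float))
    return Cohort(data=data, ln_missing_counts=dict(cohort.ln_missing_counts))


def apply_eligibility(cohort: Cohort, flags: dict[str, np.ndarray]) -> tuple[Cohort, dict[str, int]]:
    """Drop ineligible rows given per-reason boolean exclusion flags.

    Returns the filtered cohort and a per-reason count of exclusions (a row
    excluded for several reasons is counted under each).
    """
    n = cohort.n
    drop = np.zeros(n, dtype=bool)
    counts: dict[str, int] = {}
    for reason, flag in flags.items():
        flag = np.asarray(flag, dtype=bool)
        counts[reason] = int(flag.sum())
        drop |= flag
    kept = cohort.data.loc[~drop].reset_index(drop=True)
    return Cohort(data=kept, ln_missing_counts=dict(cohort.ln_missing_counts)), counts


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_phenotype_table(path, spec: PhenotypeSpec | None = None) -> Cohort:
    """Read a delimited phenotype table into a typed :class:`Cohort`.

    Required columns are mapped through ``spec.columns``; sex is recoded to a
    0/1 indicator (1 = female) via ``spec.sex_coding``.  Rows with
    unparseable numeric fields keep NaN in those fields (flagged, not
    dropped).
    """
    spec = spec or PhenotypeSpec.default()
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, na_values=list(spec.na_values),
                      keep_default_na=False)
    for canon in REQUIRED_PHENOTYPES:
        src = spec.columns.get(canon, canon)
        if src not in raw.columns:
            raise CohortError(f"missing required column {src!r} (maps to {canon!r})")
    data = pd.DataFrame()
    data["sample_id"] = raw[spec.columns.get("sample_id", "sample_id")].astype(str)
    if data["sample_id"].duplicated().any():
        dup = data["sample_id"][data["sample_id"].duplicated()].iloc[0]
        raise CohortError(f"duplicate sample_id: {dup!r}")
    sex_src = raw[spec.columns.get("sex", "sex")]
    known = sex_src.isna() | sex_src.isin(list(spec.sex_coding))
    if not known.all():
        bad = sex_src[~known].iloc[0]
        raise CohortError(f"unrecognised sex code {bad!r}")
    data["sex"] = sex_src.map(spec.sex_coding).astype(float)
    med_src = raw[spec.columns.get("on_htn_med", "on_htn_med")]
    data["on_htn_med"] = med_src.isin(list(spec.true_values)).astype(float).where(~med_src.isna(), np.nan)
    for canon, src in spec.columns.items():
        if canon in ("sample_id", "sex", "on_htn_med"):
            continue
        col = pd.to_numeric(raw[src], errors="coerce")
        parse_failed = col.isna() & ~raw[src].isna()
        if parse_failed.any():
            bad = raw[src][parse_failed].iloc[0]
            raise CohortError(f"non-numeric value {bad!r} in numeric column {src!r}")
        data[canon] = col.astype(float)
    # carry through unmapped extra columns with the same strict numeric parse;
    # columns with no numeric content at all (free-text annotations) are skipped
    mapped_srcs = set(spec.columns.values())
    for src in raw.columns:
        if src in mapped_srcs or src in data.columns:
            continue
        col = pd.to_numeric(raw[src], errors="coerce")
        parse_failed = col.isna() & ~raw[src].isna()
        if parse_failed.all():
            continue
        if parse_failed.any():
            bad = raw[src][parse_failed].iloc[0]
            raise CohortError(f"non-numeric value {bad!r} in numeric column {src!r}")
        data[src] = col.astype(float)
    return Cohort(data=data)


def write_phenotype_table(cohort: Cohort, path) -> None:
    """Deterministic TSV writer: fixed column order, %.10g floats, NA sentinel."""
    df = cohort.data.copy()
    cols = ["sample_id"] + sorted(c for c in df.columns if c != "sample_id")
    df[cols].to_csv(path, sep="\t", index=False, na_rep=NA_SENTINEL, float_format="%.10g")


def read_dosage_table(path) -> GenotypeMatrix:
    """Read a PLINK ``.raw`` additive dosage table.

    Header: ``FID IID PAT MAT SEX PHENOTYPE`` then one column per variant
    named ``<id>_<countedAllele>``; values 0/1/2/NA.  Positions/chromosomes
    are not carried by the format and are filled with placeholders; use
    :func:`read_variant_metadata` to attach a sidecar.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str, na_values=[NA_SENTINEL],
                     keep_default_na=False)
    for col in _RAW_LEADING:
        if col not in df.columns:
            raise CohortError(f"not a .raw file: missing leading column {col!r}")
    variant_cols = [c for c in df.columns if c not in _RAW_LEADING]
    ids, alleles = [], []
    for c in variant_cols:
        if "_" not in c:
            raise CohortError(f"variant header {c!r} lacks a counted-allele suffix")
        vid, allele = c.rsplit("_", 1)
        ids.append(vid)
        alleles.append(allele)
    dosages = df[variant_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    raw_vals = df[variant_cols].to_numpy()
    unexpected = np.isnan(dosages) & ~pd.isna(raw_vals)
    if unexpected.any():
        bad = raw_vals[unexpected].flat[0]
        raise CohortError(f"dosage outside {{0,1,2,NA}}: {bad!r}")
    variants = pd.DataFrame({
        "id": ids,
        "chrom": "0",
        "pos": np.arange(1, len(ids) + 1),
        "ref_allele": "N",
        "alt_allele": alleles,
        "counted_allele": alleles,
    })
    return GenotypeMatrix(dosages=dosages, variants=variants,
                          sample_ids=df["IID"].to_numpy())


def read_variant_metadata(gm: GenotypeMatrix, path) -> GenotypeMatrix:
    """Attach a sidecar variant-metadata TSV (id, chrom, pos, ref, alt)."""
    meta = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    meta = meta.set_index("id")
    variants = gm.variants.copy()
    for i, vid in enumerate(variants["id"]):
        if vid in meta.index:
            row = meta.loc[vid]
            variants.loc[i, ["chrom", "pos", "ref_allele", "alt_allele"]] = (
                str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])
    return GenotypeMatrix(dosages=gm.dosages, variants=variants, sample_ids=gm.sample_ids)


def write_dosage_table(gm: GenotypeMatrix, path, metadata_path=None) -> None:
    """Write a PLINK ``.raw``-dialect dosage table (and optional metadata sidecar)."""
    header = _RAW_LEADING + [f"{v.id}_{v.counted_allele}" for v in gm.variants.itertuples()]
    with open(path, "w") as fh:
        fh.write(" ".join(header) + "\n")
        for i, sid in enumerate(gm.sample_ids):
            lead = [str(sid), str(sid), "0", "0", "0", "-9"]
            row = [NA_SENTINEL if np.isnan(d) else str(int(d)) for d in gm.dosages[i]]
            fh.write(" ".join(lead + row) + "\n")
    if metadata_path is not None:
        meta = gm.variants.rename(columns={"ref_allele": "ref", "alt_allele": "alt"})
        meta[["id", "chrom", "pos", "ref", "alt"]].to_csv(metadata_path, sep="\t", index=False)


def align(cohort: Cohort, genotypes: GenotypeMatrix) -> tuple[Cohort, GenotypeMatrix]:
    """Restrict both tables to the sorted intersection of sample ids."""
    pheno_ids = set(map(str, cohort.sample_ids))
    geno_ids = set(map(str, genotypes.sample_ids))
    common = sorted(pheno_ids & geno_ids)
    if not common:
        raise CohortError("no overlapping sample ids between phenotypes and genotypes")
    dropped = (len(pheno_ids) - len(common)) + (len(geno_ids) - len(common))
    if dropped:
        logger.info("align: dropped %d non-overlapping samples", dropped)
    order = {sid: k for k, sid in enumerate(common)}
    pmask = np.array([str(s) in order for s in cohort.sample_ids])
    pdata = cohort.data.loc[pmask].copy()
    pdata = pdata.iloc[np.argsort([order[str(s)] for s in pdata["sample_id"]])]
    new_cohort = Cohort(data=pdata.reset_index(drop=True),
                        ln_missing_counts=dict(cohort.ln_missing_counts))
    gmask = np.array([str(s) in order for s in genotypes.sample_ids])
    gsub = genotypes.subset_samples(gmask)
    gorder = np.argsort([order[str(s)] for s in gsub.sample_ids])
    new_geno = gsub.subset_samples(gorder)
    return new_cohort, new_geno
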