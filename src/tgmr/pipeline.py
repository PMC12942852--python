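"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` executes: cohort load/simulate -> genotype QC -> additive
scan -> instrument screening -> GRS (in-sample, cross-fitted, expanded) ->
MR estimation (2SPS, 2SRI, overidentified 2SLS with Sargan/Wu-Hausman) ->
observational arm -> comparative forest table.  Every stage writes its
output under the artifact directory together with a manifest carrying the
config hash and seeds, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (Cohort, GenotypeMatrix, align, derive_ln,
                     read_dosage_table, read_phenotype_table,
                     read_variant_metadata, write_dosage_table,
                     write_phenotype_table)
from .instruments import (InstrumentSet, ScreeningRules, build_grs,
                          crossfit_grs, expanded_grs, negative_control_scan,
                          select_instruments)
from .mr import (MREstimate, sargan_test, two_sls, two_stage_ps, two_stage_ri,
                 wu_hausman_test)
from .observational import baseline_frame, baseline_table, logistic_or
from .qc import (QCThresholds, additive_scan, ld_prune, qc_pipeline,
                 sort_variants, suggestive_hits)
from .simulate import SimulationConfig, preset, simulate_cohort

logger = logging.getLogger(__name__)

EXIT_OK, EXIT_VALIDATION, EXIT_STAGE = 0, 2, 3


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline halted at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults follow the study's thresholds."""

    # inputs: either file paths or a simulation scenario
    phenotype_path: str | None = None
    genotype_path: str | None = None
    variant_metadata_path: str | None = None
    simulate: str | None = "causal"            # scenario name, or None for files
    simulate_overrides: dict = field(default_factory=dict)
    # covariate sets
    scan_covars: tuple[str, ...] = ("age", "sex")
    weight_covars: tuple[str, ...] = ("age", "sex", "bmi")
    # thresholds
    qc: QCThresholds = field(default_factory=QCThresholds)
    prune_window: int = 250
    prune_step: int = 50
    prune_r2: float = 0.5
    suggestive_alpha: float = 1e-5
    screen_alpha: float = 0.05
    f_min: float = 10.0
    k_folds: int = 10
    bootstrap_B: int = 0                       # 0 disables bootstrap CIs
    exposure_column: str = "tg"                # ln-transformed internally
    seed: int = 0
    out_dir: str = "tgmr_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["qc"] = dataclasses.asdict(self.qc)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCThresholds(**d["qc"])
        for key in ("scan_covars", "weight_covars"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: Path
    cohort: Cohort
    genotypes: GenotypeMatrix
    instrument_set: InstrumentSet
    estimates: list[MREstimate]
    forest: pd.DataFrame
    diagnostics: dict


def _load_or_simulate(config: PipelineConfig):
    if config.simulate:
        sim = preset(config.simulate, seed=config.seed, **config.simulate_overrides)
        cohort, genotypes, truth = simulate_cohort(sim)
        return cohort, genotypes, truth
    if not (config.phenotype_path and config.genotype_path):
        raise ValueError("need phenotype_path and genotype_path when not simulating")
    cohort = read_phenotype_table(config.phenotype_path)
    genotypes = read_dosage_table(config.genotype_path)
    if config.variant_metadata_path:
        genotypes = read_variant_metadata(genotypes, config.variant_metadata_path)
    cohort, genotypes = align(cohort, genotypes)
    return cohort, genotypes, None


def forest_table(rows: list[dict]) -> pd.DataFrame:
    """Figure-style comparative table: observational rows first, then per-SNP,
    then GRS variants; crude before adjusted within a label."""
    order = {"observational": 0, "snp": 1, "grs": 2}
    df = pd.DataFrame(rows)
    df["_k"] = df["kind"].map(order)
    df = df.sort_values(["_k", "label", "model"]).drop(columns="_k")
    return df.reset_index(drop=True)


def render_forest(df: pd.DataFrame) -> str:
    """Fixed-width text rendering of the forest table (OR and CI to 2 dp)."""
    lines = [f"{'label':<18}{'model':<10}{'type':<15}{'OR':>7}  {'95% CI':<15}{'p':>8}"]
    for r in df.itertuples():
        ci = f"({r.ci_low:.2f}-{r.ci_high:.2f})"
        lines.append(f"{r.label:<18}{r.model:<10}{r.kind:<15}{r.or_value:>7.2f}"
                     f"  {ci:<15}{r.p:>8.3f}")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = {"tgmr_version": __version__, "config": config.to_dict(),
                "config_hash": _config_hash(config), "seed": config.seed,
                "stages": []}

    def _save_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    def stage(name):
        manifest["stages"].append(name)
        _save_manifest()
        logger.info("stage: %s", name)

    try:
        stage("cohort")
        cohort, genotypes, truth = _load_or_simulate(config)
        if config.exposure_column not in cohort.data.columns:
            raise ValueError(f"missing exposure column {config.exposure_column!r}")
        if f"ln_{config.exposure_column}" not in cohort.data.columns:
            cohort = derive_ln(cohort, config.exposure_column)
        exposure = f"ln_{config.exposure_column}"
        write_phenotype_table(cohort, out / "phenotypes.tsv")
        write_dosage_table(genotypes, out / "dosages.raw", out / "variants.tsv")
        if truth is not None:
            (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2))
    except Exception as e:
        _save_manifest()
        raise StageError("cohort", e) from e

    try:
        stage("qc")
        genotypes, qc_report = qc_pipeline(genotypes, config.qc)
        (out / "qc_report.json").write_text(json.dumps(qc_report.to_dict(), indent=2))
    except Exception as e:
        raise StageError("qc", e) from e

    try:
        stage("scan")
        scan = additive_scan(genotypes, cohort, exposure, config.scan_covars)
        scan_df = pd.DataFrame([vars(s) for s in scan])
        scan_df.to_csv(out / "scan.tsv", sep="\t", index=False,
                       float_format="%.6g", na_rep="NA")
    except Exception as e:
        raise StageError("scan", e) from e

    try:
        stage("screen")
        pruned, prune_report = ld_prune(sort_variants(genotypes), config.prune_window,
                                        config.prune_step, config.prune_r2)
        hits = [h for h in suggestive_hits(scan, config.suggestive_alpha)
                if h in set(pruned.variant_ids)]
        rules = ScreeningRules(f_min=config.f_min, screen_alpha=config.screen_alpha,
                               covariate_set=config.weight_covars)
        iset = select_instruments(hits, cohort, genotypes, rules, exposure)
        iset.table().to_csv(out / "instruments.tsv", sep="\t", index=False)
        with open(out / "audit.jsonl", "w") as fh:
            for row in iset.audit:
                fh.write(json.dumps(vars(row), default=str) + "\n")
        # candidates excluded only by the direct-outcome screen are eligible
        # for the expanded-GRS sensitivity analysis
        strong = {r.variant_id for r in iset.audit
                  if r.check == "strength" and r.passed}
        direct_failed = [r.variant_id for r in iset.audit
                         if r.check == "direct_outcome" and not r.passed
                         and r.variant_id in strong
                         and r.variant_id not in set(iset.ids)]
    except Exception as e:
        raise StageError("screen", e) from e

    try:
        stage("grs")
        grs = build_grs(genotypes, iset)
        cf = crossfit_grs(genotypes, cohort, iset.ids, config.k_folds,
                          config.seed, config.weight_covars, exposure)
    except Exception as e:
        raise StageError("grs", e) from e

    try:
        stage("mr")
        estimates: list[MREstimate] = []
        rows: list[dict] = []
        inst_cols = {v.variant_id: genotypes.column(v.variant_id)
                     for v in iset.variants}
        for model, covars in (("crude", ()), ("adjusted", config.weight_covars)):
            for vid, z in inst_cols.items():
                est = two_stage_ps(cohort, z, covars, exposure, label=vid)
                estimates.append(est)
                rows.append(_forest_row(est, "snp", model))
            for label, vec in (("GRS", grs.scores), ("crossfit-GRS", cf.scores)):
                est = two_stage_ps(cohort, vec, covars, exposure, label=label)
                estimates.append(est)
                rows.append(_forest_row(est, "grs", model))
            est = two_stage_ri(cohort, grs.scores, covars, exposure, label="GRS")
            estimates.append(est)
        if direct_failed:
            try:
                expanded = expanded_grs(genotypes, cohort, iset,
                                        direct_failed[0],
                                        exposure=exposure)
                exp_scores = build_grs(genotypes, expanded).scores
                est = two_stage_ps(cohort, exp_scores, config.weight_covars,
                                   exposure, label="expanded-GRS")
                estimates.append(est)
                rows.append(_forest_row(est, "grs", "adjusted"))
            except ValueError as e:
                logger.info("expanded GRS skipped: %s", e)
        z_all = np.column_stack(list(inst_cols.values()))
        tsls = two_sls(cohort, z_all, config.weight_covars, exposure, label="2SLS")
        estimates.append(tsls)
        diagnostics = {}
        if z_all.shape[1] >= 2:
            s_stat, s_df, s_p = sargan_test(tsls)
            wh_stat, wh_p = wu_hausman_test(cohort, z_all, config.weight_covars,
                                            exposure)
            diagnostics = {"sargan": {"stat": s_stat, "df": s_df, "p": s_p},
                           "wu_hausman": {"stat": wh_stat, "p": wh_p},
                           "two_sls_estimate": tsls.estimate,
                           "two_sls_se": tsls.se}
        (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
    except Exception as e:
        raise StageError("mr", e) from e

    try:
        stage("observational")
        for model, covars in (("crude", None), ("adjusted", config.weight_covars)):
            orv, (lo, hi), p = logistic_or(cohort, exposure, covars=covars)
            rows.append({"label": "measured ln(TG)", "model": model,
                         "kind": "observational", "or_value": orv,
                         "ci_low": lo, "ci_high": hi, "p": p, "n": cohort.n,
                         "first_stage_f": np.nan})
        spec = [(v, True) for v in ("tg", "glucose", "insulin", "hdl_c")
                if v in cohort.data.columns]
        base = baseline_frame(baseline_table(cohort, spec))
        base.to_csv(out / "baseline.tsv", sep="\t", index=False,
                    float_format="%.6g")
        negatives = negative_control_scan(
            iset, cohort, genotypes,
            [b for b in ("hdl_c", "ldl_c", "apoa1", "apob", "hs_crp")
             if b in cohort.data.columns],
            config.weight_covars)
        negatives.to_csv(out / "negative_controls.tsv", sep="\t", index=False,
                         float_format="%.6g")
    except Exception as e:
        raise StageError("observational", e) from e

    try:
        stage("report")
        forest = forest_table(rows)
        forest.to_csv(out / "forest.tsv", sep="\t", index=False,
                      float_format="%.6g")
        (out / "forest.txt").write_text(render_forest(forest) + "\n")
        _save_manifest()
    except Exception as e:
        raise StageError("report", e) from e

    return PipelineResult(out_dir=out, cohort=cohort, genotypes=genotypes,
                          instrument_set=iset, estimates=estimates,
                          forest=forest, diagnostics=diagnostics)


def _forest_row(est: MREstimate, kind: str, model: str) -> dict:
    return {"label": est.instrument, "model": model, "kind": kind,
            "or_value": est.or_value, "ci_low": est.or_ci_low,
            "ci_high": est.or_ci_high, "p": est.p, "n": est.n,
            "first_stage_f": est.first_stage_f}
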