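import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tgmr.instruments import (NoValidInstrumentsError, ScreeningRules,
                              build_grs, check_covariate_independence,
                              check_outcome_direct, crossfit_grs,
                              expanded_grs, instrument_strength,
                              negative_control_scan, partial_r2_from_f,
                              select_instruments)
from tgmr.mr import first_stage, ols_fit
from tgmr.simulate import preset, simulate_cohort
from conftest import make_cohort, make_genotypes


class TestStrengthArithmetic:
    @pytest.mark.parametrize("f_stat,n,k_covars,expected", [
        # adjusted first-stage models: df = n - 5 (intercept + snp + 3 covars)
        (21.2, 2149, 3, 0.010),
        (17.9, 2151, 3, 0.008),
        (21.7, 2150, 3, 0.010),
        (42.7, 2133, 3, 0.020),
        # unadjusted models: df = n - 2
        (23.4, 2149, 0, 0.011),
        (17.0, 2151, 0, 0.008),
        (18.0, 2150, 0, 0.008),
        (42.2, 2133, 0, 0.019),
    ])
    def test_partial_r2_identity(self, f_stat, n, k_covars, expected):
        df = n - (k_covars + 2)
        assert round(partial_r2_from_f(f_stat, df), 3) == expected

    def test_zero_f_zero_r2(self):
        assert partial_r2_from_f(0.0, 100) == 0.0

    @given(f1=st.floats(0.01, 1e4), f2=st.floats(0.01, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_f(self, f1, f2):
        df = 500
        lo, hi = sorted([f1, f2])
        assert partial_r2_from_f(lo, df) <= partial_r2_from_f(hi, df)
        assert partial_r2_from_f(1e12, df) > 0.999999

    def test_equals_nested_model_f(self):
        rng = np.random.default_rng(0)
        n = 30
        g = rng.binomial(2, 0.4, n).astype(float)
        df = pd.DataFrame({
            "ln_tg": 4.7 + 0.3 * g + rng.normal(0, 0.4, n),
            "age": rng.normal(50, 8, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "bmi": rng.normal(24, 3, n)})
        cohort = make_cohort(df)
        beta, se, t, F, pr2, n_used = instrument_strength(g, cohort)
        C = np.column_stack([np.ones(n), df["age"], df["sex"], df["bmi"]])
        full = np.column_stack([C, g])
        r0 = ols_fit(C, df["ln_tg"]).residuals
        r1 = ols_fit(full, df["ln_tg"]).residuals
        rss0, rss1 = r0 @ r0, r1 @ r1
        F_nested = (rss0 - rss1) / (rss1 / (n - 5))
        assert F == pytest.approx(F_nested, abs=1e-8)
        assert pr2 == pytest.approx((rss0 - rss1) / rss0, abs=1e-8)


def _screen_cohort(seed=0, n=4000):
    rng = np.random.default_rng(seed)
    age = rng.normal(50, 10, n)
    sex = rng.integers(0, 2, n).astype(float)
    bmi = rng.normal(24, 3, n)
    df = pd.DataFrame({"age": age, "sex": sex, "bmi": bmi})
    return df, rng


class TestCovariateIndependence:
    def test_independent_dosage_passes_mostly(self):
        df, rng = _screen_cohort(1)
        df["ln_tg"] = rng.normal(4.7, 0.45, len(df))
        g = rng.binomial(2, 0.3, len(df)).astype(float)
        rows = check_covariate_independence(g, make_cohort(df))
        assert len(rows) == 3
        assert all(np.isfinite(r.p) for r in rows)

    def test_planted_age_association_fails(self):
        df, rng = _screen_cohort(2)
        g = np.clip(np.round(df["age"] / 40), 0, 2).to_numpy()
        rows = check_covariate_independence(g, make_cohort(df))
        age_row = [r for r in rows if r.check.endswith("age")][0]
        assert not age_row.passed

    def test_constant_dosage_degenerate(self):
        df, _ = _screen_cohort(3)
        rows = check_covariate_independence(np.ones(len(df)), make_cohort(df))
        assert len(rows) == 1
        assert rows[0].reason == "degenerate"

    def test_nominal_failure_rate(self):
        # under independence the per-candidate failure rate is ~1-(1-a)^3
        df, rng = _screen_cohort(4, n=800)
        failures = 0
        reps = 200
        for _ in range(reps):
            g = rng.binomial(2, 0.3, len(df)).astype(float)
            rows = check_covariate_independence(g, make_cohort(df))
            failures += not all(r.passed for r in rows)
        expected = 1 - 0.95 ** 3
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(failures / reps - expected) < 4 * se


class TestOutcomeDirect:
    def test_pleiotropic_snp_fails(self, causal_theta0):
        cfg = preset("pleiotropic", n=10_000, seed=5, n_null_snps=0,
                     pleiotropy_delta=0.3, missing_rate=0.0)
        cohort, geno, _ = simulate_cohort(cfg)
        row = check_outcome_direct(geno.dosages[:, cfg.pleiotropic_index],
                                   cohort, variant_id="plei")
        assert not row.passed
        assert row.reason in ("direct_association", "direction_inconsistent")

    def test_null_snp_passes_at_nominal_rate(self):
        df, rng = _screen_cohort(6, n=2000)
        df["ln_tg"] = rng.normal(4.7, 0.45, len(df))
        df["htn"] = rng.binomial(1, 0.25, len(df)).astype(float)
        cohort = make_cohort(df)
        fails = sum(
            not check_outcome_direct(
                rng.binomial(2, 0.3, len(df)).astype(float), cohort).passed
            for _ in range(200))
        assert 1 <= fails <= 25  # ~5% nominal

    def test_direction_inconsistent_reason(self):
        # strong protective direct effect on the outcome, oriented TG-increasing
        df, rng = _screen_cohort(7, n=8000)
        g = rng.binomial(2, 0.3, len(df)).astype(float)
        p = 1 / (1 + np.exp(-(-1.1 - 0.5 * g)))
        df["htn"] = (rng.random(len(df)) < p).astype(float)
        df["ln_tg"] = 4.7 + 0.1 * g + rng.normal(0, 0.45, len(df))
        row = check_outcome_direct(g, make_cohort(df), tg_increasing_sign=1.0)
        assert not row.passed
        assert row.reason == "direction_inconsistent"

    def test_constant_dosage_degenerate(self):
        df, rng = _screen_cohort(8)
        df["htn"] = rng.binomial(1, 0.3, len(df)).astype(float)
        row = check_outcome_direct(np.zeros(len(df)), make_cohort(df))
        assert row.reason == "degenerate"


class TestSelectInstruments:
    def _setup(self, seed=9):
        cfg = preset("causal", seed=seed, n_null_snps=0, missing_rate=0.0)
        return simulate_cohort(cfg)

    def test_planted_instruments_retained(self, causal_theta0):
        # at study scale the planted instruments have expected first-stage
        # F of roughly 13-22, so each clears F > 10 with probability
        # ~0.7-0.93 and also faces the ~0.81 joint pass rate of the four
        # alpha=0.05 screens; the retained set must always be a subset of
        # the planted ids with a plausible average count
        retained = []
        for seed in range(8):
            cohort, geno, _ = self._setup(seed)
            try:
                iset = select_instruments(["iv0", "iv1", "iv2"], cohort, geno)
                assert set(iset.ids) <= {"iv0", "iv1", "iv2"}
                assert all(v.f_stat > 10 for v in iset.variants)
                retained.append(len(iset.variants))
            except NoValidInstrumentsError:
                retained.append(0)
        assert np.mean(retained) >= 1.2

    def test_weak_instrument_rejected_with_reason(self):
        rng = np.random.default_rng(10)
        n = 2000
        g = rng.binomial(2, 0.3, n).astype(float)
        df = pd.DataFrame({
            "ln_tg": 4.7 + 0.02 * g + rng.normal(0, 0.45, n),  # F ~ 1
            "age": rng.normal(50, 10, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "bmi": rng.normal(24, 3, n),
            "htn": rng.binomial(1, 0.25, n).astype(float)})
        cohort = make_cohort(df)
        gm = make_genotypes(g[:, None], ids=["weak1"])
        with pytest.raises(NoValidInstrumentsError):
            select_instruments(["weak1"], cohort, gm)
        # the audit trail is still accessible through a passing sibling
        g2 = rng.binomial(2, 0.3, n).astype(float)
        df2 = df.copy()
        df2["ln_tg"] = 4.7 + 0.3 * g2 + rng.normal(0, 0.45, n)
        gm2 = make_genotypes(np.column_stack([g, g2]), ids=["weak1", "strong1"])
        iset = select_instruments(["weak1", "strong1"], make_cohort(df2), gm2)
        weak_rows = [r for r in iset.audit
                     if r.variant_id == "weak1" and r.check == "strength"]
        assert weak_rows and weak_rows[0].reason == "weak"
        assert iset.ids == ["strong1"]

    def test_orientation_makes_weights_positive(self):
        rng = np.random.default_rng(11)
        n = 3000
        g = rng.binomial(2, 0.4, n).astype(float)
        df = pd.DataFrame({
            "ln_tg": 4.7 - 0.25 * g + rng.normal(0, 0.45, n),  # TG-decreasing
            "age": rng.normal(50, 10, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "bmi": rng.normal(24, 3, n),
            "htn": rng.binomial(1, 0.25, n).astype(float)})
        gm = make_genotypes(g[:, None], ids=["snpneg"])
        iset = select_instruments(["snpneg"], make_cohort(df), gm)
        v = iset.variants[0]
        assert v.weight > 0
        assert v.flipped
        assert v.counted_allele == "A"  # flipped from counted G to other allele


class TestGrs:
    def test_unit_weights_count_alleles(self):
        from tgmr.instruments import InstrumentSet, InstrumentVariant
        rng = np.random.default_rng(12)
        d = rng.binomial(2, 0.3, size=(20, 3)).astype(float)
        gm = make_genotypes(d)
        iset = InstrumentSet(
            variants=[InstrumentVariant(f"v{j}", "G", 1.0, 1.0, 0.1, 20, 0.01, 20)
                      for j in range(3)],
            audit=[], covariate_set=())
        grs = build_grs(gm, iset)
        np.testing.assert_allclose(grs.scores, d.sum(axis=1))

    def test_hand_computed_scores(self):
        from tgmr.instruments import InstrumentSet, InstrumentVariant
        d = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 0, 0], [2, 2, 2.0]])
        w = [0.145, 0.069, 0.072]
        gm = make_genotypes(d)
        iset = InstrumentSet(
            variants=[InstrumentVariant(f"v{j}", "G", w[j], w[j], 0.03, 20, 0.01, 5)
                      for j in range(3)],
            audit=[], covariate_set=())
        grs = build_grs(gm, iset)
        # spreadsheet arithmetic
        expected = [0.069 + 2 * 0.072, 0.145 + 0.069, 2 * 0.145 + 0.072,
                    0.0, 2 * (0.145 + 0.069 + 0.072)]
        np.testing.assert_allclose(grs.scores, expected, atol=1e-12)

    def test_missing_genotype_excluded(self):
        from tgmr.instruments import InstrumentSet, InstrumentVariant
        d = np.array([[0, 1], [np.nan, 2], [1, 1.0]])
        gm = make_genotypes(d)
        iset = InstrumentSet(
            variants=[InstrumentVariant(f"v{j}", "G", 1.0, 1.0, 0.1, 20, 0.01, 3)
                      for j in range(2)],
            audit=[], covariate_set=())
        grs = build_grs(gm, iset)
        assert np.isnan(grs.scores[1])
        assert grs.n_complete == 2

    def test_absent_instrument_errors(self):
        from tgmr.instruments import InstrumentSet, InstrumentVariant
        gm = make_genotypes(np.zeros((3, 1)))
        iset = InstrumentSet(
            variants=[InstrumentVariant("ghost", "G", 1.0, 1.0, 0.1, 20, 0.01, 3)],
            audit=[], covariate_set=())
        with pytest.raises(KeyError):
            build_grs(gm, iset)


class TestCrossfit:
    def test_same_seed_reproducible(self, causal_draw):
        cohort, geno, _ = causal_draw
        a = crossfit_grs(geno, cohort, ["iv0", "iv1", "iv2"], K=5, seed=3)
        b = crossfit_grs(geno, cohort, ["iv0", "iv1", "iv2"], K=5, seed=3)
        np.testing.assert_array_equal(a.scores, b.scores)
        np.testing.assert_array_equal(a.fold_id, b.fold_id)
        assert a.weight_provenance == "out-of-fold"

    def test_pathological_k_rejected(self):
        cfg = preset("causal", n=40, seed=14, n_null_snps=0, missing_rate=0.0)
        cohort, geno, _ = simulate_cohort(cfg, theta0=-4.0)
        with pytest.raises(ValueError):
            crossfit_grs(geno, cohort, ["iv0"], K=20, seed=0)
        with pytest.raises(ValueError):
            crossfit_grs(geno, cohort, ["iv0"], K=1, seed=0)

    def test_homogeneous_weights_match_insample(self):
        # near-noiseless first stage: fold weights agree, scores align
        cfg = preset("causal", n=4000, seed=15, n_null_snps=0,
                     exposure_sd=0.01, gamma_u=0.0, missing_rate=0.0)
        cohort, geno, _ = simulate_cohort(cfg, theta0=-4.0)
        iset = select_instruments(["iv0", "iv1", "iv2"], cohort, geno,
                                  ScreeningRules(screen_alpha=1e-12))
        in_sample = build_grs(geno, iset)
        cf = crossfit_grs(geno, cohort, iset.ids, K=5, seed=1)
        ok = np.isfinite(in_sample.scores) & np.isfinite(cf.scores)
        r = np.corrcoef(in_sample.scores[ok], cf.scores[ok])[0, 1]
        assert r > 0.99


class TestExpandedGrs:
    def _with_extra(self, delta=0.4, seed=16):
        cfg = preset("causal", n=6000, seed=seed, n_null_snps=0,
                     instrument_mafs=(0.05, 0.15, 0.2, 0.27),
                     instrument_betas=(0.145, 0.069, 0.072, 0.25),
                     pleiotropy_delta=delta, pleiotropic_index=3,
                     missing_rate=0.0)
        cohort, geno, _ = simulate_cohort(cfg, theta0=-4.6)
        iset = select_instruments(["iv0", "iv1", "iv2"], cohort, geno,
                                  ScreeningRules(screen_alpha=0.01))
        return cohort, geno, iset

    def test_partial_f_strictly_increases(self):
        cohort, geno, iset = self._with_extra()
        base = build_grs(geno, iset)
        expanded = expanded_grs(geno, cohort, iset, "iv3")
        grown = build_grs(geno, expanded)
        fs_base = first_stage(cohort, base.scores, ("age", "sex", "bmi"))
        fs_grown = first_stage(cohort, grown.scores, ("age", "sex", "bmi"))
        assert fs_grown.extra["F"] > fs_base.extra["F"]

    def test_sensitivity_flag_in_audit(self):
        cohort, geno, iset = self._with_extra()
        expanded = expanded_grs(geno, cohort, iset, "iv3")
        assert expanded.variants[-1].sensitivity_only
        assert any(r.reason == "sensitivity_only" for r in expanded.audit)

    def test_collinear_extra_rejected(self):
        cohort, geno, iset = self._with_extra()
        dup = geno.variants.copy()
        first = iset.ids[0]
        import pandas as pd
        from tgmr.cohort import GenotypeMatrix
        col = geno.column(first)
        dosages = np.hstack([geno.dosages, col[:, None]])
        variants = pd.concat([geno.variants, pd.DataFrame([{
            "id": "twin", "chrom": "1", "pos": 999_999,
            "ref_allele": "A", "alt_allele": "G", "counted_allele": "G"}])],
            ignore_index=True)
        geno2 = GenotypeMatrix(dosages=dosages, variants=variants,
                               sample_ids=geno.sample_ids)
        with pytest.raises(ValueError, match="collinear"):
            expanded_grs(geno2, cohort, iset, "twin")

    def test_weak_extra_rejected(self):
        cohort, geno, iset = self._with_extra()
        rng = np.random.default_rng(0)
        import pandas as pd
        from tgmr.cohort import GenotypeMatrix
        noise = rng.binomial(2, 0.3, geno.n_samples).astype(float)
        dosages = np.hstack([geno.dosages, noise[:, None]])
        variants = pd.concat([geno.variants, pd.DataFrame([{
            "id": "noise", "chrom": "1", "pos": 999_999,
            "ref_allele": "A", "alt_allele": "G", "counted_allele": "G"}])],
            ignore_index=True)
        geno2 = GenotypeMatrix(dosages=dosages, variants=variants,
                               sample_ids=geno.sample_ids)
        with pytest.raises(ValueError, match="strength"):
            expanded_grs(geno2, cohort, iset, "noise")


class TestNegativeControls:
    def test_independent_biomarker_uniform_p(self):
        from scipy import stats as sps
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(150):
            n = 500
            g = rng.binomial(2, 0.3, n).astype(float)
            df = pd.DataFrame({
                "ln_tg": 4.7 + rng.normal(0, 0.45, n),
                "age": rng.normal(50, 10, n),
                "sex": rng.integers(0, 2, n).astype(float),
                "bmi": rng.normal(24, 3, n),
                "marker": rng.normal(0, 1, n)})
            from tgmr.instruments import InstrumentSet, InstrumentVariant
            gm = make_genotypes(g[:, None], ids=["snp"])
            iset = InstrumentSet(
                variants=[InstrumentVariant("snp", "G", 0.1, 0.1, 0.03, 15, 0.01, n)],
                audit=[], covariate_set=("age", "sex", "bmi"))
            tab = negative_control_scan(iset, make_cohort(df), gm, ["marker"])
            pvals.append(tab["p"].iloc[0])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_exposure_itself_flagged(self, causal_draw):
        from tgmr.instruments import InstrumentSet, InstrumentVariant
        cohort, geno, _ = causal_draw
        iset = InstrumentSet(
            variants=[InstrumentVariant("iv0", "G", 0.145, 0.145, 0.03, 20, 0.01,
                                        cohort.n)],
            audit=[], covariate_set=("age", "sex", "bmi"))
        tab = negative_control_scan(iset, cohort, geno, ["ln_tg"])
        assert tab["p"].iloc[0] < 0.01

    def test_empty_biomarker_list(self, causal_draw):
        from tgmr.instruments import InstrumentSet, InstrumentVariant
        cohort, geno, _ = causal_draw
        iset = InstrumentSet(
            variants=[InstrumentVariant("iv0", "G", 0.145, 0.145, 0.03, 20, 0.01,
                                        cohort.n)],
            audit=[], covariate_set=())
        tab = negative_control_scan(iset, cohort, geno, [])
        assert len(tab) == 0
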