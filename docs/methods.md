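# Methods

## The analysis problem

In observational data, serum triglycerides (TG) and hypertension are
strongly associated, but TG tracks broader cardiometabolic dysregulation
(adiposity, insulin resistance), so the association is confounded and
potentially reverse-causal.  One-sample Mendelian randomization (MR) uses
genetic variants as instruments for ln(TG): alleles are fixed at conception,
so a variant that (i) predicts ln(TG), (ii) is independent of confounders,
and (iii) affects hypertension only through TG identifies the causal effect.
`tgmr` implements that design end to end for individual-level data, together
with the conventional observational arm it is contrasted with.

## Estimators

Let Y be hypertension (binary), X = ln(TG), C = (age, sex, BMI), Z the
instrument (a SNP dosage or a weighted score).

* First stage: OLS of `X ~ 1 + Z + C` on complete cases.  For the single
  instrument term, partial F = t² and partial R² = t²/(t² + df),
  df = n − (#covariates + 2).  These identities make published strength
  columns mutually derivable, and the package exposes them directly
  (`partial_r2_from_f`).
* 2SPS: logistic `Y ~ 1 + X̂ + C`.  With a nonlinear second stage this is an
  approximation to the conditional causal odds ratio (noncollapsibility
  attenuates it toward the null); it is nevertheless the standard primary
  specification for binary outcomes in this design.
* 2SRI: logistic `Y ~ 1 + X + ê + C` with the raw additive first-stage
  residual ê — the control-function form.
* 2SLS: linear-probability IV with C as included instruments.  The solution
  is computed as the least-squares fit of Y on the Z-projected regressors
  (QR route; X̂'X = X̂'X̂ makes this exact), with classical standard errors
  by default and HC0 behind a flag — classical errors keep the Sargan and
  Wu–Hausman statistics in their textbook forms.
* Sargan: n·R² from regressing the 2SLS residual on all instruments and
  covariates, χ² with df = #instruments − 1; undefined (raises) when
  just-identified.
* Wu–Hausman: t²-form test of the first-stage residual coefficient in the
  augmented outcome regression.
* With a *linear* second stage, 2SPS ≡ 2SRI ≡ 2SLS exactly for one
  endogenous regressor; the suite verifies agreement to 1e-10 on random
  instances, which pins all three implementations to one another.

Uncertainty for 2SPS/2SRI is naive Wald from the second-stage fit by
default; a nonparametric case-resampling bootstrap that reruns both stages
per replicate is available (`bootstrap_ci`).  The Wald form ignores
first-stage estimation noise and is therefore mildly anticonservative in
principle; at the weak-instrument strengths simulated here the measured
type-I error stays within [0.03, 0.07] (asserted in the suite).

## Instrument workflow

Candidates come from an additive per-SNP scan of ln(TG) adjusted for age
and sex, thresholded at the suggestive p < 1e-5.  LD pruning (greedy,
250-variant window, step 50, pairwise r² ≤ 0.5, later variant removed,
per chromosome) is applied only at instrument selection.  Screens, each
producing an audit row: strength F > 10; independence from age, sex
(logistic) and BMI at α = 0.05; no covariate-adjusted direct association
with hypertension at α = 0.05, with a significant *opposite-signed*
association recorded as `direction_inconsistent` (the pattern that excludes
a strong TG variant whose direct hypertension association contradicts a
TG-raising instrument).  The direct-association screen necessarily also
rejects strong valid instruments at large n, since the mediated path is a
real association — a conservative, documented property.  α = 0.05 and
K = 10 folds are package choices where the design leaves them open; both
are configurable.

Weights are the first-stage coefficients from the age/sex/BMI-adjusted
model; dosages are oriented so each weight is positive (risk-allele
counting).  The cross-fitted GRS uses outcome-stratified folds; each fold's
individuals are scored with weights estimated on the other folds.  One
property deserves emphasis: fold-level held-out tests of the score-exposure
association are exactly sized, but the fold statistics are mutually
*correlated* (their training sets overlap), so pooling cross-fitted scores
into a single naive test remains anticonservative.  `crossfit_heldout_test`
therefore reports per-fold statistics, and the calibration property is
asserted on a single designated fold per replicate.

## Synthetic cohort generator

The generator is the package's study-conditions stand-in for a private
cohort; it emulates the data's statistical structure, not its biology.

* Genotypes: dosage ~ Binomial(2, MAF) per variant, independent (HWE holds
  by construction).  Instruments: MAFs (0.05, 0.15, 0.20), per-allele
  ln(TG) effects (0.145, 0.069, 0.072).  Null SNPs (default 500 — enough to
  exercise QC and the scan at desk scale) have MAFs uniform on (0.05, 0.5).
* Covariates: age ~ N(50, 10) truncated to [20, 86]; 40% male; BMI ~
  N(24 + 0.02(age − 50), 3).  Confounder U ~ N(0, 1), unobserved.
* Exposure: ln(TG) = 4.7 + Σβⱼgⱼ + 0.008·age_c − 0.18·female +
  0.035·BMI_c + 0.2·U + ε, ε ~ N(0, 0.3938²).  The residual
  (post-covariate) variance is fixed at 0.20 ln-units².  With the fixed
  betas this puts the per-SNP partial R² at ≈ 0.010 / 0.006 / 0.008 and the
  combined score at ≈ 0.024: the published per-SNP band (0.008–0.011) and
  the combined 0.020 cannot all hold simultaneously under any single
  residual variance, so the residual variance was chosen once to bracket
  both and is not tuned thereafter.
* Outcome: htn ~ Bernoulli(expit(θ₀ + θ_TG·ln TG + 0.06·age_c −
  0.40·female + 0.15·BMI_c + 0.5·U + δ·g_pleiotropic)).  θ₀ is calibrated
  by monotone root-finding (Brent) on a fixed 100 000-draw Monte-Carlo
  sample with an internal fixed seed, hitting the 25.2% prevalence target
  within ±0.005.  With all effects zero this reduces to logit(p) exactly.
* Presets: `null` (θ_TG = 0, no confounding), `causal` (θ_TG = ln 2),
  `confounded_null` (θ_TG = 0, U active — crude observational OR inflated),
  `pleiotropic` (causal plus δ = 0.15 direct log-odds per allele on the
  third instrument, about three times its mediated effect).
* Missingness: independent entry-wise at 0.004, matching per-SNP analysis
  sample sizes around 2149–2151 of 2159.
* Blood-pressure columns are generated *consistently with* the already-drawn
  outcome (hypertensives get SBP ≥ 140, DBP ≥ 90 or a medication flag), so
  the classification rule round-trips; they carry no independent signal.
* Everything is a pure function of config + seed; derived sub-seeds stay
  below 2³¹.  The TruthRecord (true θ_TG, θ₀, U, realized prevalence) is
  available to tests only and never appears in analysis-facing tables.

What the generator does **not** emulate: linkage disequilibrium beyond
constructed correlated duplicates (used only to test pruning), population
stratification, genotyping error, assortative mating, non-log-normal TG
tails, medication effects on TG.  Passing tests therefore demonstrate
correctness of the estimators and the workflow under the assumed structure,
not robustness to those real-data features.

## Simulation sizes and numerical choices

Property checks run at sizes chosen for stable verdicts at desk scale:
type-I error of the 2SPS Wald test, 500 replicates at n = 2159 (binomial
99% bounds around 0.05); Sargan uniformity, 1000 replicates at n = 2000
(KS at α = 0.01); Sargan and direct-screen power against the planted
pleiotropic instrument, 60 replicates at n = 10⁴ (both powers exceed 0.95
analytically at δ = 0.15, so 60 suffices); 2SLS recovery with strengthened
instruments (betas scaled to first-stage R² ≈ 0.3), 200 replicates at
n = 10⁴; cross-fitting calibration, 500 replicates with K = 5.

Logistic fits use the statsmodels Newton MLE (tol 1e-10, 100 iterations);
non-convergence or |coef| > 50 raises an explicit separation error.  OLS is
a QR/lstsq solve with an explicit rank check that names collinear columns
and refuses zero residual degrees of freedom.  95% intervals use
z = 1.959964; all p-values are two-sided.  Complete-case filtering is per
analysis (no imputation), so each estimate records its own n; the em-dash
not-applicable marker is returned whenever a variable appears in its own
covariate set.  HWE uses the exact conditional test (χ² behind a flag);
the "250" in the pruning parameters is read as a 250-variant window, and
ties prefer the earlier variant, matching the common tool convention.
Glucose mg/dL→mmol/L conversion uses divisor 18.016 (molar mass 180.16).

## Known limitations

2SPS/2SRI odds ratios are noncollapsible approximations; the Wald CI
ignores first-stage noise (bootstrap available); the direct-outcome screen
is conservative for strong instruments; diagnostics (Sargan, Wu–Hausman)
have little power at the study's instrument strength — the suite
demonstrates their calibration and their power only at n = 10⁴; and the
linear-probability 2SLS can produce fitted probabilities outside [0, 1],
which is accepted for diagnostic purposes as usual.
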