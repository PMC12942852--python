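"""The full causal contrast: MR estimators versus observational regression.

Runs 2SPS (primary), 2SRI (control function) and the overidentified linear
2SLS with Sargan/Wu-Hausman diagnostics, next to crude and adjusted
observational odds ratios for measured ln(TG).
"""

import logging

import numpy as np

from tgmr.mr import (first_stage, sargan_test, two_sls, two_stage_ps,
                     two_stage_ri, wu_hausman_test)
from tgmr.observational import logistic_or
from tgmr.simulate import preset, simulate_cohort

logging.disable(logging.WARNING)
covars = ("age", "sex", "bmi")

cfg = preset("causal", seed=6, n_null_snps=0)   # true OR = 2.0 per ln(TG)
cohort, geno, truth = simulate_cohort(cfg)
g = geno.dosages[:, :3]

w = np.array([first_stage(cohort, g[:, j], covars).coef[1] for j in range(3)])
score = np.where(np.isfinite(g).all(axis=1), np.nan_to_num(g) @ w, np.nan)

crude, (c_lo, c_hi), _ = logistic_or(cohort, "ln_tg")
adj, (a_lo, a_hi), _ = logistic_or(cohort, "ln_tg", covars=covars)
print(f"observational OR per ln(TG): crude {crude:.2f} ({c_lo:.2f}-{c_hi:.2f}), "
      f"adjusted {adj:.2f} ({a_lo:.2f}-{a_hi:.2f})")

ps = two_stage_ps(cohort, score, covars, label="GRS")
ri = two_stage_ri(cohort, score, covars, label="GRS")
print(f"MR 2SPS (GRS): OR {ps.or_value:.2f} ({ps.or_ci_low:.2f}-"
      f"{ps.or_ci_high:.2f}), p={ps.p:.3f}, first-stage F={ps.first_stage_f:.1f}")
print(f"MR 2SRI (GRS): OR {np.exp(ri.estimate):.2f}, p={ri.p:.3f}")

tsls = two_sls(cohort, g, covars)
s_stat, s_df, s_p = sargan_test(tsls)
wh_stat, wh_p = wu_hausman_test(cohort, g, covars)
print(f"2SLS (linear probability): slope {tsls.estimate:+.3f} per ln(TG)")
print(f"Sargan overidentification p={s_p:.3f} (df={s_df}); "
      f"Wu-Hausman endogeneity p={wh_p:.3f}")
print(f"[truth: causal OR {np.exp(truth.theta_tg):.2f}; the MR CI is wide "
      "because the instruments explain ~2% of ln(TG) variance]")
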