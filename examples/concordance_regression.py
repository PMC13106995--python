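"""Concordance regressions: zygosity effects, pooled samples, FDR.

Three analyses on simulated cohorts:

1. co-twin syndrome status regressed on zygosity (plain logistic, adjusted
   for co-twin sex and age), in the near-single-ascertainment regime where
   every pair contributes one proband unit;
2. the same regression pooling three samples of different sizes and
   baseline concordances, with sample as a random intercept (mixed
   logistic via adaptive Gauss-Hermite quadrature);
3. whether negative/disorganised syndromes in the proband predict MZ
   concordance for the narrow positive syndrome (delusions plus
   hallucinations), with Benjamini-Hochberg FDR over the four predictors.
"""

import numpy as np
import pandas as pd

from twinliab import (SeparationError, SimulationParams, TwoPathwayPreset,
                      bh_fdr, derive_profiles, expand_units, fit_logistic,
                      fit_logistic_glmm, simulate_ascertained_cohort)
from twinliab.regression import build_concordance_design
from twinliab.syndromes import derive_subsyndromes


def units_for(params):
    prof = derive_subsyndromes(derive_profiles(simulate_ascertained_cohort(params)))
    return prof, expand_units(prof, "pos2")


# 1. zygosity as a predictor of narrow-positive concordance
params = SimulationParams(a2=0.7, c2=0.0, K=0.02, n_mz=20000, n_dz=20000,
                          theta_both=1.0, ascertainment_prob=0.2, seed=11)
_, units = units_for(params)
X = build_concordance_design(
    units, {"zygosity_mz": (units["zygosity"] == "MZ").to_numpy(float)})
res = fit_logistic(units["cotwin_affected"].to_numpy(float), X)
print("co-twin pos2 ~ zygosity + co-twin sex + co-twin age (logistic)")
print(res.summary_frame().round(4).to_string(), "\n")

# 2. three pooled samples, sample as a random intercept
frames = []
for s, (a2, n) in enumerate([(0.5, 12000), (0.7, 20000), (0.85, 8000)]):
    p = SimulationParams(a2=a2, c2=0.0, K=0.02, n_mz=n, n_dz=n,
                         theta_both=1.0, ascertainment_prob=0.2,
                         sample_id=f"S{s + 1}", seed=30 + s)
    frames.append(units_for(p)[1])
pooled = pd.concat(frames, ignore_index=True)
Xp = build_concordance_design(
    pooled, {"zygosity_mz": (pooled["zygosity"] == "MZ").to_numpy(float)})
mixed = fit_logistic_glmm(pooled["cotwin_affected"].to_numpy(float), Xp,
                          {"sample": pooled["sample_id"].to_numpy()}, nodes=21)
print("pooled samples, sample random intercept (mixed logistic)")
print(mixed.summary_frame().round(4).to_string())
print(f"sample random-intercept variance: {mixed.re_var['sample']:.3f}\n")

# 3. proband subsyndrome predictors of MZ concordance, BH-FDR adjusted
tp = SimulationParams(
    a2=0.5, c2=0.0, K=0.01, n_mz=60000, n_dz=0, theta_both=1.0,
    ascertainment_prob=0.9, seed=11,
    two_pathway=TwoPathwayPreset(a2_low=0.2, a2_high=0.9, mix_weight=0.5))
prof, mz_units = units_for(tp)
proband_status = prof.set_index("individual_id")
pvals, labels = [], []
for predictor in ("neg_broad", "neg_narrow", "dis_broad", "dis_narrow"):
    status = proband_status.loc[mz_units["proband_id"], predictor] \
        .astype("boolean").fillna(False).to_numpy(dtype=float)
    Xs = build_concordance_design(mz_units, {predictor: status})
    try:
        reg = fit_logistic(mz_units["cotwin_affected"].to_numpy(float), Xs)
    except SeparationError as err:
        # too few probands with the predictor phenotype: no finite MLE
        print(f"proband {predictor:<11s}: {err}")
        continue
    j = reg.names.index(predictor)
    print(f"proband {predictor:<11s}: OR {reg.odds_ratios[j]:6.2f} "
          f"(95% CI {reg.or_ci[j, 0]:.2f}-{reg.or_ci[j, 1]:.2f}), "
          f"p = {reg.pvalues[j]:.4f}")
    pvals.append(reg.pvalues[j])
    labels.append(predictor)

fdr = bh_fdr(np.array(pvals), q=0.05)
kept = [lab for lab, rej in zip(labels, fdr.rejected) if rej]
print(f"\nBH-FDR (q=0.05) over the four predictors rejects: {kept or 'none'}")
print("An OR > 1 in part 3 means higher narrow-positive concordance when the"
      "\nproband also shows that syndrome — driven here by the simulated"
      "\nhigh-heritability pathway coupling positive and disorganised symptoms.")
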