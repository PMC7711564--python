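"""Covariate-adjusted protein-adiposity associations with FDR control.

Each standardized protein is regressed on BMI (per 1 reference SD = 3.4
units) with the full covariate adjustment; the panel is controlled at a 5%
false-discovery rate and summarized by an ordered-p-value band.
"""

import pandas as pd

from adipomr import SimConfig, assoc_panel, exclude_low_detect, make_study, renyi_band, standardize
from adipomr.observational import OBSERVATIONAL_ADJUSTMENT

cfg = SimConfig(n_gwas=8000, n_subcohort=700, n_variants=100, n_variants_rare=12, seed=3)
cohort, truth = make_study(cfg)

retained, dropped = exclude_low_detect(cohort.proteins, cohort.lod_flags)
print(f"{len(dropped)} proteins >99% below the limit of detection excluded "
      f"({', '.join(dropped['protein'])}); {len(retained)} analyzed")

sub = cohort.covariates.loc[cohort.subcohort_ids].copy()
sub["bmi_z"] = standardize(sub["bmi"], reference_sd=cfg.exposure_sd)
panel_z = cohort.proteins[retained].apply(standardize)
data = pd.concat([sub, panel_z], axis=1)

results = assoc_panel(data, retained, "bmi_z", OBSERVATIONAL_ADJUSTMENT, fdr_q=0.05)
n_sig = int(results["significant_fdr"].sum())
_, n_band = renyi_band(results["p"].to_numpy(), q=0.05)
print(f"{n_sig} of {len(results)} proteins associated with BMI at 5% FDR; "
      f"{n_band} surpass the ordered-p band")
top = results.nsmallest(5, "p")[["trait", "beta", "ci_low", "ci_high", "p_adjusted"]]
print("\nstrongest associations (SD protein per 1-SD BMI):")
print(top.to_string(index=False))
# Betas near the truth-set values indicate the adjustment recovers the
# simulated exposure effects despite confounding.
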