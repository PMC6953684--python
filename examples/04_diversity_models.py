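"""Diversity stages: gall richness/abundance vs site and vs leaf traits.

Per-plant gall counts are modelled with a Poisson GLM on site (quasi-
Poisson when overdispersed) and with a Poisson mixed model (random site
intercept) on specific leaf mass, tested by likelihood-ratio chi-square.
"""

import warnings

warnings.filterwarnings("ignore")

from nullcooc import fit_diversity_models, fit_trait_mixed_model, simulate_gradient_study

study = simulate_gradient_study(seed=19)
records = study.all_gall_records()

fits = fit_diversity_models(records)
print("per-plant gall counts vs site (deviance analysis):")
for resp, f in fits.items():
    print(f"  {f.label:18s} family={f.family:12s} deviance={f.deviance:7.2f} "
          f"{f.statistic_name}={f.statistic:7.2f}  df={f.df}  p={f.p_value:.3g}")

mixed = fit_trait_mixed_model(records, study.sfm_by_plant(), response="richness")
print(f"\n{mixed.label}: slope={mixed.coefficients['sfm']:+.4f} "
      f"sigma_site={mixed.coefficients['sigma_site']:.3f} "
      f"LR chi2={mixed.statistic:.2f} p={mixed.p_value:.3g}")
print("\nThe site term captures the planted diversity gradient (richer, denser"
      "\ngall loads under stress); the mixed model asks whether leaf"
      "\nsclerophylly explains plant-to-plant variation beyond site effects.")
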