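"""Full stress-gradient analysis on a simulated seven-site study.

Simulates the whole design — seven sites from mesic to xeric, one
12-species x 137-leaflet matrix each, with segregation planted only in the
xeric half — then runs the complete pipeline: per-site null-model tests,
soil PCA, aridity and sclerophylly indicators, and the NES-vs-stress
regressions.
"""

import warnings

warnings.filterwarnings("ignore")

from nullcooc import RunConfig, analyze_gradient_study, simulate_gradient_study, stress_models_table

study = simulate_gradient_study(n_sites=7, theta_max=1.5, seed=11)
result = analyze_gradient_study(study, RunConfig(n_null=1_000, burn_in=10_000, thin=2_000, seed=5))

pc_var = result.soil.variance_fractions
print(f"soil PCA: first two axes explain {100 * (pc_var[0] + pc_var[1]):.1f}% of variance\n")

print("per-site indicators and co-occurrence results")
print("(stress rises from site01 to site07; theta = 1.5 in the xeric half):")
print(result.indicators.round(4).to_string(index=False))

print("\nNES ~ stress-indicator regressions (Gaussian, deviance F test):")
print(stress_models_table(result.stress_fits).round(4).to_string(index=False))

print("\nExpected pattern: xeric sites get small p_ge (segregation detected),"
      "\nNES rises with specific leaf mass and falls with the aridity index"
      "\nand with soil fertility (PC1), mirroring competition intensifying"
      "\nwith environmental stress.")
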