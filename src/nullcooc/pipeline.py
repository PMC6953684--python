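"""End-to-end orchestration of the multi-site gradient analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import CoocResult, RunConfig, analyze_site
from .matrix import drop_empty_species, filter_galled_leaflets
from .stress import ModelFit, SoilPCA, attach_soil_pc1, fit_stress_models
from .synthetic import SyntheticStudy

__all__ = ["GradientResult", "analyze_gradient_study", "stress_models_table"]


@dataclass
class GradientResult:
    cooc_results: list[CoocResult]
    soil: SoilPCA
    stress_fits: dict[str, ModelFit]  # keyed by indicator: sfm, aridity, soil_pc1
    indicators: pd.DataFrame  # per-site sfm mean, AI, soil PC1, NES


def analyze_gradient_study(
    study: SyntheticStudy, config: RunConfig | None = None
) -> GradientResult:
    """Run the full pipeline on a (typically simulated) gradient study.

    Per site: filter to galled leaflets, drop absent species, run the
    fixed-fixed co-occurrence test. Across sites: soil PCA, aridity index
    and mean sfm, then the three Gaussian regressions of NES on the stress
    indicators.
    """
    config = config or RunConfig()
    results = []
    for m in study.matrices:
        m = drop_empty_species(filter_galled_leaflets(m))
        results.append(analyze_site(m, config))
    pca = attach_soil_pc1(study.environments)
    sfm_means = study.sfm_means()
    fits = fit_stress_models(results, study.environments, sfm_means)
    indicators = pd.DataFrame(
        {
            "site": [r.site_id for r in results],
            "nes": [r.nes for r in results],
            "ses": [np.nan if r.ses is None else r.ses for r in results],
            "p_ge": [r.p_ge for r in results],
            "sfm_mean": [sfm_means[r.site_id] for r in results],
            "aridity_index": [e.aridity_index for e in study.environments],
            "soil_pc1": [e.soil_pc1 for e in study.environments],
        }
    )
    return GradientResult(results, pca, fits, indicators)


def stress_models_table(fits: dict[str, ModelFit]) -> pd.DataFrame:
    """Deviance-analysis table of the stress regressions (one row per model)."""
    rows = []
    for name, f in fits.items():
        rows.append(
            {
                "response": "nes_c_score",
                "explanatory": name,
                "slope": f.coefficients.get("slope", np.nan),
                "deviance": f.deviance,
                "residual_deviance": f.residual_deviance,
                "df": f"{f.df[0]},{f.df[1]}",
                f.statistic_name: f.statistic,
                "p": f.p_value,
            }
        )
    return pd.DataFrame(rows)
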