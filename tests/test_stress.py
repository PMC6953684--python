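import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from nullcooc import (
    LeafDiskRecord,
    PlantGallRecord,
    SiteEnvironment,
    aridity_index,
    fit_diversity_models,
    fit_stress_models,
    fit_trait_mixed_model,
    soil_pca,
    specific_leaf_mass,
)
from nullcooc.stress import SOIL_VARIABLES, attach_soil_pc1, fit_gaussian_glm


def _env(p, pet, site="s"):
    return SiteEnvironment(
        site_id=site,
        monthly_precip=np.asarray(p, dtype=float),
        monthly_pet=np.asarray(pet, dtype=float),
        soil_chemistry=pd.Series(1.0, index=list(SOIL_VARIABLES)),
    )


class TestAridityIndex:
    def test_equal_series_gives_one(self):
        assert aridity_index(_env([80] * 24, [80] * 24)) == pytest.approx(1.0)

    def test_two_month_toy(self):
        assert aridity_index(([100, 50], [100, 100])) == pytest.approx(0.75)

    def test_homogeneous_in_precip(self):
        p = np.linspace(40, 160, 24)
        pet = np.full(24, 90.0)
        assert aridity_index((2 * p, pet)) == pytest.approx(2 * aridity_index((p, pet)))

    def test_decreasing_in_pet(self):
        p = np.full(24, 80.0)
        assert aridity_index((p, np.full(24, 110.0))) < aridity_index((p, np.full(24, 100.0)))

    def test_totals_aggregation_option(self):
        assert aridity_index(([100, 50], [100, 100]), method="totals") == pytest.approx(0.75)
        assert aridity_index(([10, 190], [100, 100]), method="totals") == pytest.approx(1.0)

    def test_nonpositive_pet_errors(self):
        with pytest.raises(ValueError, match="PET"):
            aridity_index(([10, 10], [100, 0]))

    def test_missing_months_reported(self):
        with pytest.raises(ValueError, match="positions \\[1\\]"):
            aridity_index(([10, np.nan], [100, 100]))


class TestSpecificLeafMass:
    def test_disk_arithmetic(self):
        assert specific_leaf_mass(3.8) == pytest.approx(10.0)  # 3.8 mg / 0.38 cm^2

    def test_zero_mass(self):
        assert specific_leaf_mass(0.0) == 0.0

    def test_linear_in_mass(self):
        assert specific_leaf_mass(7.6) == pytest.approx(2 * specific_leaf_mass(3.8))

    def test_negative_mass_errors(self):
        with pytest.raises(ValueError):
            LeafDiskRecord("p", "s", -1.0)


class TestSoilPCA:
    @pytest.fixture
    def soil_table(self):
        rng = np.random.default_rng(5)
        stress = np.linspace(0, 1, 7)
        data = {}
        for k, var in enumerate(SOIL_VARIABLES):
            direction = -1 if var in ("H+Al", "Al3+", "m") else 1
            data[var] = direction * stress + 0.05 * rng.normal(size=7) + k
        return pd.DataFrame(data, index=[f"site{i}" for i in range(7)])

    def test_variance_fractions_sum_to_one(self, soil_table):
        pca = soil_pca(soil_table)
        assert pca.variance_fractions.sum() == pytest.approx(1.0)

    def test_rank_one_case(self):
        x = np.linspace(0, 1, 3)
        table = pd.DataFrame({"a": x, "b": 2 * x + 1, "V": 3 * x})
        pca = soil_pca(table)
        assert pca.variance_fractions[0] == pytest.approx(1.0)

    def test_reconstruction(self, soil_table):
        pca = soil_pca(soil_table)
        x = soil_table.to_numpy()
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
        assert np.allclose(recon, z, atol=1e-10)

    def test_fertile_positive_orientation(self, soil_table):
        pca = soil_pca(soil_table)
        assert pca.loadings.loc["V", "PC1"] > 0

    def test_constant_variable_named(self, soil_table):
        soil_table["Mg"] = 3.0
        with pytest.raises(ValueError, match="Mg"):
            soil_pca(soil_table)

    def test_too_few_sites(self, soil_table):
        with pytest.raises(ValueError, match="3 sites"):
            soil_pca(soil_table.iloc[:2])


class TestGaussianStage:
    def test_exact_linear_response_recovers_slope(self):
        x = np.linspace(0, 1, 7)
        fit = fit_gaussian_glm(0.2 + 1.5 * x, x)
        assert fit.coefficients["slope"] == pytest.approx(1.5)
        assert fit.residual_deviance == pytest.approx(0.0, abs=1e-12)
        assert fit.p_value < 1e-6

    def test_constant_indicator_errors(self):
        with pytest.raises(ValueError, match="constant"):
            fit_gaussian_glm(np.arange(5.0), np.ones(5))

    def test_stress_models_use_site_level_df(self):
        from types import SimpleNamespace

        rng = np.random.default_rng(0)
        envs = []
        for i, stress in enumerate(np.linspace(0, 1, 7)):
            e = _env(
                (1.2 - stress) * np.full(24, 100.0), np.full(24, 100.0), site=f"s{i}"
            )
            e.soil_chemistry = pd.Series(
                {v: (1 - stress) * 2 + 0.01 * rng.normal() + j for j, v in enumerate(SOIL_VARIABLES)}
            )
            envs.append(e)
        attach_soil_pc1(envs)
        results = [
            SimpleNamespace(site_id=f"s{i}", nes=0.01 * stress + 0.001 * rng.normal())
            for i, stress in enumerate(np.linspace(0, 1, 7))
        ]
        sfm_means = {f"s{i}": 8 + 7 * s for i, s in enumerate(np.linspace(0, 1, 7))}
        fits = fit_stress_models(results, envs, sfm_means)
        assert set(fits) == {"sfm", "aridity", "soil_pc1"}
        assert all(f.df == (1, 5) for f in fits.values())
        assert fits["sfm"].coefficients["slope"] > 0
        assert fits["aridity"].coefficients["slope"] < 0


def _diversity_records(rng, means_by_site, n_plants=15):
    records = []
    for site, mean in means_by_site.items():
        for p in range(n_plants):
            rich = int(rng.poisson(mean))
            extra = int(rng.poisson(mean))
            records.append(
                PlantGallRecord(f"{site}-p{p}", site, rich, rich + extra)
            )
    return records


class TestDiversityModels:
    def test_planted_site_effect_detected(self):
        rng = np.random.default_rng(8)
        records = _diversity_records(rng, {"mesic": 2.0, "xeric": 4.0})
        fits = fit_diversity_models(records)
        assert fits["richness"].p_value < 0.05
        assert fits["richness"].df[0] == 1

    def test_null_site_effect_p_roughly_uniform(self):
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(40):
            records = _diversity_records(rng, {"a": 3.0, "b": 3.0})
            pvals.append(fit_diversity_models(records, responses=("richness",))["richness"].p_value)
        assert 0.02 < np.mean(np.array(pvals) < 0.5) < 0.85  # no systematic rejection
        assert np.mean(np.array(pvals) < 0.05) < 0.2

    def test_deviance_grows_with_effect_size(self):
        rng = np.random.default_rng(10)
        devs = []
        for ratio in (1.0, 1.5, 2.0, 3.0):
            records = _diversity_records(rng, {"a": 2.0, "b": 2.0 * ratio}, n_plants=40)
            devs.append(fit_diversity_models(records, responses=("richness",))["richness"].deviance)
        assert devs == sorted(devs)

    def test_overdispersed_counts_use_quasipoisson(self):
        rng = np.random.default_rng(11)
        records = []
        for site, mean in {"a": 2.0, "b": 4.0}.items():
            for p in range(30):
                lam = mean * rng.gamma(0.4, 1 / 0.4)  # strongly overdispersed
                rich = int(rng.poisson(lam))
                records.append(PlantGallRecord(f"{site}-p{p}", site, rich, rich * 2))
        fit = fit_diversity_models(records, responses=("richness",))["richness"]
        assert fit.family == "quasipoisson"
        assert fit.statistic_name == "F"

    def test_all_zero_response_errors(self):
        records = [PlantGallRecord(f"p{i}", f"s{i % 2}", 0, 0) for i in range(8)]
        with pytest.raises(ValueError, match="all-zero"):
            fit_diversity_models(records, responses=("richness",))


class TestTraitMixedModel:
    def _dataset(self, slope, seed=0, n_sites=6, n_plants=12):
        rng = np.random.default_rng(seed)
        records, sfm = [], {}
        for s in range(n_sites):
            u = rng.normal(0, 0.3)
            for p in range(n_plants):
                pid = f"s{s}-p{p}"
                x = rng.normal(11, 2)
                lam = np.exp(0.8 + slope * (x - 11) + u)
                rich = int(rng.poisson(lam))
                records.append(PlantGallRecord(pid, f"s{s}", rich, rich + int(rng.poisson(lam))))
                sfm[pid] = x
        return records, sfm

    def test_lr_statistic_nonnegative_and_null_calibrated(self):
        records, sfm = self._dataset(slope=0.0, seed=1)
        fit = fit_trait_mixed_model(records, sfm)
        assert fit.statistic >= 0
        assert fit.p_value > 0.01

    def test_strong_effect_detected(self):
        records, sfm = self._dataset(slope=0.25, seed=2)
        fit = fit_trait_mixed_model(records, sfm)
        assert fit.p_value < 0.01
        assert fit.coefficients["sfm"] > 0

    def test_single_site_errors(self):
        records = [PlantGallRecord(f"p{i}", "only", 1, 2) for i in range(10)]
        with pytest.raises(ValueError, match="single site"):
            fit_trait_mixed_model(records, {f"p{i}": 10.0 for i in range(10)})

    def test_matches_lme4_glmer(self, tmp_path):
        """Cross-check the quadrature ML fit against lme4::glmer (nAGQ=25)."""
        records, sfm = self._dataset(slope=0.12, seed=3, n_sites=5, n_plants=10)
        fit = fit_trait_mixed_model(records, sfm)
        df = pd.DataFrame(
            {
                "y": [r.richness for r in records],
                "sfm_c": [sfm[r.plant_id] for r in records],
                "site": [r.site_id for r in records],
            }
        )
        df["sfm_c"] -= df["sfm_c"].mean()
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        r_code = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m  <- glmer(y ~ sfm_c + (1|site), data=d, family=poisson, nAGQ=25)
            m0 <- glmer(y ~ 1 + (1|site), data=d, family=poisson, nAGQ=25)
            cat(fixef(m)[["sfm_c"]], 2*(logLik(m)-logLik(m0)), "\\n")
            """
        )
        proc = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        r_slope, r_lr = map(float, proc.stdout.split())
        assert fit.coefficients["sfm"] == pytest.approx(r_slope, abs=2e-3)
        assert fit.statistic == pytest.approx(r_lr, abs=0.05)
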