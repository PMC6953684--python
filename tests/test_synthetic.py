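import numpy as np
import pytest

from nullcooc import (
    CommunitySimConfig,
    c_score,
    filter_galled_leaflets,
    simulate_gall_community,
    simulate_gradient_study,
    simulate_site_environment,
    soil_pca,
)
from nullcooc.stress import SOIL_VARIABLES
from nullcooc.synthetic import pair_competition_weights
import pandas as pd
from scipy import stats


class TestCommunitySimulation:
    def test_deterministic_for_seed(self):
        cfg = CommunitySimConfig(n_species=6, n_leaflets=30, theta=0.8, seed=3)
        a = simulate_gall_community(cfg)
        b = simulate_gall_community(cfg)
        assert np.array_equal(a.values, b.values)

    def test_every_leaflet_galled(self):
        for theta in (-0.5, 0.0, 1.5):
            cfg = CommunitySimConfig(n_species=9, n_leaflets=60, theta=theta, seed=11)
            m = simulate_gall_community(cfg)
            assert (m.col_totals >= 1).all()
            f = filter_galled_leaflets(m)
            assert np.array_equal(f.values, m.values)

    def test_exclusion_limit_two_species(self):
        cfg = CommunitySimConfig(
            n_species=2, n_leaflets=80, theta=50.0,
            base_occupancy=np.array([0.4, 0.4]), seed=2,
        )
        m = simulate_gall_community(cfg)
        shared = int((m.values[0] & m.values[1]).sum())
        assert shared == 0
        r1, r2 = m.row_totals
        assert c_score(m) == r1 * r2  # CU attains its maximum for the margins

    def test_rejection_sampler_matches_model(self):
        """Large community path (rejection) also leaves no leaflet empty."""
        cfg = CommunitySimConfig(n_species=18, n_leaflets=50, theta=0.5, seed=4)
        m = simulate_gall_community(cfg)
        assert m.n_species == 18
        assert (m.col_totals >= 1).all()

    def test_rejection_sampler_rejects_aggregation(self):
        cfg = CommunitySimConfig(n_species=18, n_leaflets=30, theta=-0.5, seed=4)
        with pytest.raises(ValueError, match="exact sampler"):
            simulate_gall_community(cfg)

    def test_uniform_weights_are_margin_absorbed(self):
        """Homogeneous interaction only shifts column totals, not structure:
        conditional on margins the law stays uniform, so the mean C-score
        shift against the fixed-margin null is ~0 (checked via NES elsewhere);
        here we check the weights themselves."""
        q = np.array([0.1, 0.2, 0.4])
        w = pair_competition_weights(q, "uniform")
        assert np.all(w[np.triu_indices(3, 1)] == 1.0)
        w_enc = pair_competition_weights(q, "encounter")
        assert w_enc[1, 2] > w_enc[0, 1]  # abundant pairs compete harder
        assert np.allclose(w_enc, w_enc.T) and np.all(np.diag(w_enc) == 0)

    def test_theta_zero_matches_independent_conditional_law(self):
        """At θ=0 each leaflet's pattern follows independent Bernoulli
        conditioned on non-emptiness: check single-species occupancy against
        the closed form q_s' = q_s-ish via a binomial tolerance."""
        q = np.array([0.3, 0.3])
        cfg = CommunitySimConfig(
            n_species=2, n_leaflets=4000, theta=0.0, base_occupancy=q, seed=9
        )
        m = simulate_gall_community(cfg)
        # P(pattern) for non-empty patterns {10, 01, 11}
        p_full = np.array([0.3 * 0.7, 0.7 * 0.3, 0.09])
        p_full /= p_full.sum()
        counts = np.array(
            [
                int(((m.values[0] == 1) & (m.values[1] == 0)).sum()),
                int(((m.values[0] == 0) & (m.values[1] == 1)).sum()),
                int(((m.values[0] == 1) & (m.values[1] == 1)).sum()),
            ]
        )
        assert stats.chisquare(counts, f_exp=p_full * 4000).pvalue > 0.001


class TestSiteEnvironment:
    def test_noise_off_monotonicity(self):
        env0, disks0 = simulate_site_environment(0.0, seed=1, noise=0.0)
        env1, disks1 = simulate_site_environment(1.0, seed=1, noise=0.0)
        assert env0.aridity_index > env1.aridity_index
        assert np.mean([d.sfm for d in disks0]) < np.mean([d.sfm for d in disks1])
        for var in ("Ca", "Mg", "K", "P", "SB", "V"):
            assert env0.soil_chemistry[var] > env1.soil_chemistry[var]
        for var in ("Al3+", "H+Al", "m"):
            assert env0.soil_chemistry[var] < env1.soil_chemistry[var]

    def test_noise_off_pc1_rank_correlates_with_fertility(self):
        stress = np.linspace(0, 1, 7)
        envs = [simulate_site_environment(s, seed=0, noise=0.0, site_id=f"s{i}")[0]
                for i, s in enumerate(stress)]
        table = pd.DataFrame({e.site_id: e.soil_chemistry for e in envs}).T
        pca = soil_pca(table)
        rho = stats.spearmanr(pca.scores["PC1"], 1 - stress).statistic
        assert rho == pytest.approx(1.0)

    def test_deterministic_for_seed(self):
        a_env, a_disks = simulate_site_environment(0.4, seed=6)
        b_env, b_disks = simulate_site_environment(0.4, seed=6)
        assert np.array_equal(a_env.monthly_precip, b_env.monthly_precip)
        assert [d.disk_dry_mass_mg for d in a_disks] == [d.disk_dry_mass_mg for d in b_disks]

    def test_invalid_stress_errors(self):
        with pytest.raises(ValueError):
            simulate_site_environment(1.2)


@pytest.fixture(scope="module")
def study():
    return simulate_gradient_study(seed=21)


class TestGradientStudy:
    def test_design_dimensions(self, study):
        assert len(study.sites) == 7
        for s in study.sites:
            assert s.matrix.n_leaflets == 137
            assert len(s.gall_records) == 15
            assert (s.matrix.col_totals >= 1).all()

    def test_theta_step_design(self, study):
        thetas = [s.theta for s in study.sites]
        stresses = [s.stress_level for s in study.sites]
        for th, st_level in zip(thetas, stresses):
            assert th == (1.5 if st_level > 0.5 else 0.0)
        # xeric theta >= mesic theta everywhere
        assert min(t for t, s in zip(thetas, stresses) if s > 0.5) >= max(
            t for t, s in zip(thetas, stresses) if s <= 0.5
        )

    def test_plant_records_consistent_with_matrix(self, study):
        for s in study.sites:
            total_richness_bound = s.matrix.n_species
            for r in s.gall_records:
                assert 1 <= r.richness <= total_richness_bound
                assert r.richness <= r.abundance

    def test_richness_rises_with_stress(self):
        """Planted occupancy gain: mean per-plant richness higher in the
        xeric half (averaged over a few replicates to beat sampling noise)."""
        xeric, mesic = [], []
        for seed in range(5):
            study = simulate_gradient_study(seed=100 + seed)
            for s in study.sites:
                mean_rich = np.mean([r.richness for r in s.gall_records])
                (xeric if s.stress_level > 0.5 else mesic).append(mean_rich)
        assert np.mean(xeric) > np.mean(mesic)

    def test_ground_truth_recorded(self, study):
        gt = study.ground_truth
        assert gt["theta_max"] == 1.5
        assert set(gt["theta_by_site"]) == {s.site_id for s in study.sites}


def test_write_study_round_trips_through_loaders(tmp_path):
    from nullcooc import load_matrix, write_study
    from nullcooc.stress import load_climate_csv, load_gall_csv, load_leaf_csv, load_soil_csv

    study = simulate_gradient_study(n_sites=3, n_species=5, n_leaflets=20, seed=2)
    write_study(study, tmp_path)
    envs = load_climate_csv(tmp_path / "climate.csv")
    soil = load_soil_csv(tmp_path / "soil.csv")
    disks = load_leaf_csv(tmp_path / "leaf.csv")
    galls = load_gall_csv(tmp_path / "galls.csv")
    assert set(envs) == {s.site_id for s in study.sites}
    assert list(soil.columns) == list(SOIL_VARIABLES)
    assert len(disks) == sum(len(s.leaf_disks) for s in study.sites)
    assert len(galls) == 3 * 15
    m = load_matrix(tmp_path / "matrix_site01.csv", site_id="site01")
    assert np.array_equal(m.values, study.sites[0].matrix.values)
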