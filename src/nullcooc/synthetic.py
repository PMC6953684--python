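"""Synthetic gall-community and stress-gradient generator.

Every pipeline stage can be exercised without field data: the generator
emulates the study design the analyses assume — seven sites along a
stress gradient, 15 host plants per site, one binary species x 137-leaflet
matrix per site in which every leaflet hosts at least one gall — with a
known, tunable pairwise segregation strength.

Community model
---------------
Each leaflet's species set X in {0,1}^S is drawn independently from a
pairwise-interaction (Markov-random-field) distribution

    P(X = x)  ∝  exp( Σ_s x_s logit(q_s)  −  θ Σ_{s<t} w_st x_s x_t ),

conditioned on Σ x_s >= 1 (only galled leaflets are sampled). θ > 0
penalizes co-occupation (segregation), θ = 0 recovers exact independence
given non-emptiness (the calibration null), θ < 0 rewards it
(aggregation).

The pair weights w_st matter. With uniform weights (w_st = 1 for every
pair) the interaction term is θ Σ_j c_j(c_j - 1)/2, a function of the
column totals alone, so conditional on both margins the matrix is uniform
for ANY θ — a fixed-fixed test has exactly zero power against that
alternative. Worse, because Σ_pairs S_st is itself fixed by the column
totals, any redistribution of shared leaflets that is uncorrelated with
abundance cancels at first order in the C-score. The default weights are
therefore encounter-rate weights, w_st = q_s q_t / mean(q)^2: interference
competition is strongest between the abundant, frequently-encountering
morphospecies, and θ reads as the co-occurrence penalty for an
average-abundance pair. ``competition_weights="uniform"`` retains the
margin-absorbed variant for demonstrating the degeneracy.

Leaflets are sampled exactly: for <= 16 species all 2^S occupancy
patterns are enumerated and drawn from directly; for larger communities a
rejection sampler from the independent proposal is used (θ >= 0 only).

Environmental model
-------------------
Site stress s in [0,1] drives every covariate monotonically, mirroring the
xeric/mesic contrasts of tropical stress gradients: the aridity index
falls with s, soil fertility (Ca, Mg, P, K, SB, V, pH) falls while acidity
(H+Al, Al3+, m) rises, and specific leaf mass rises (plants get more
sclerophyllous). All planted slopes are recorded as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import PresenceAbsenceMatrix
from .stress import DISK_AREA_CM2, LeafDiskRecord, PlantGallRecord, SiteEnvironment, SOIL_VARIABLES

__all__ = [
    "CommunitySimConfig",
    "SyntheticSite",
    "SyntheticStudy",
    "simulate_gall_community",
    "simulate_site_environment",
    "simulate_gradient_study",
    "write_study",
]

#: soil chemistry endpoints: value at stress 0 (fertile) -> stress 1 (poor).
#: units follow routine soil reports: pH in water; H+Al, Al3+, Ca, Mg, SB, t
#: in cmolc/dm3; P in mg/dm3; K in mg/dm3; m and V in percent.
SOIL_GRADIENT: dict[str, tuple[float, float]] = {
    "pH": (6.2, 4.5),
    "H+Al": (2.0, 9.0),
    "Al3+": (0.1, 1.8),
    "Ca": (3.5, 0.4),
    "Mg": (1.2, 0.15),
    "P": (12.0, 2.0),
    "K": (90.0, 25.0),
    "SB": (5.0, 0.6),
    "t": (5.1, 2.4),
    "m": (2.0, 70.0),
    "V": (60.0, 12.0),
}

#: aridity index endpoints (stress 0 -> 1); humid > 1, semi-arid < 0.5
AI_RANGE = (1.3, 0.3)
#: site-mean specific leaf mass endpoints, mg/cm^2 (mesophyll -> sclerophyll)
SFM_RANGE = (8.0, 15.0)


#: largest community for which leaflet patterns are enumerated exactly
EXACT_ENUMERATION_MAX_SPECIES = 16


@dataclass(frozen=True)
class CommunitySimConfig:
    """Parameters of one site's community matrix simulation."""

    n_species: int = 12
    n_leaflets: int = 137
    theta: float = 0.0  # pairwise interaction: >0 segregation, <0 aggregation
    base_occupancy: np.ndarray | None = None  # per-species q_s; None => drawn
    occupancy_range: tuple[float, float] = (0.05, 0.4)  # log-uniform draw bounds
    competition_weights: str = "encounter"  # or "uniform" (margin-absorbed)
    seed: int = 0
    site_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.n_leaflets < self.n_species:
            raise ValueError("need at least as many leaflets as species")
        if self.competition_weights not in ("encounter", "uniform"):
            raise ValueError(f"unknown competition_weights {self.competition_weights!r}")
        if self.base_occupancy is not None:
            q = np.asarray(self.base_occupancy, dtype=float)
            if q.shape != (self.n_species,) or ((q <= 0) | (q >= 1)).any():
                raise ValueError("base_occupancy must be n_species values in (0, 1)")


def _draw_occupancy(cfg: CommunitySimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.base_occupancy is not None:
        return np.asarray(cfg.base_occupancy, dtype=float)
    lo, hi = cfg.occupancy_range
    # log-uniform: mimics the right-skewed occupancy of gall morphospecies
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=cfg.n_species))


def pair_competition_weights(q: np.ndarray, mode: str = "encounter") -> np.ndarray:
    """Symmetric zero-diagonal weight matrix w_st of the interaction term.

    ``encounter``: w_st = q_s q_t / mean(q)^2, so interference scales with
    how often two morphospecies meet and θ is the penalty for an
    average-abundance pair. ``uniform``: w_st = 1, retained to demonstrate
    that a homogeneous penalty is absorbed by the fixed margins.
    """
    q = np.asarray(q, dtype=float)
    if mode == "encounter":
        w = np.outer(q, q) / float(q.mean()) ** 2
    elif mode == "uniform":
        w = np.ones((q.size, q.size))
    else:
        raise ValueError(f"unknown competition_weights {mode!r}")
    np.fill_diagonal(w, 0.0)
    return w


def _leaflet_patterns_exact(
    q: np.ndarray, w: np.ndarray, theta: float, n_leaflets: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact per-leaflet sampling by enumerating all non-empty patterns."""
    s_n = q.size
    codes = np.arange(1, 2**s_n, dtype=np.int64)  # non-empty subsets
    x = ((codes[:, None] >> np.arange(s_n)[None, :]) & 1).astype(float)
    logit = np.log(q) - np.log1p(-q)
    pairs_w = 0.5 * np.einsum("bi,ij,bj->b", x, w, x)
    logp = x @ logit - theta * pairs_w
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    drawn = rng.choice(codes.size, size=n_leaflets, p=p)
    return x[drawn].astype(np.int8)


def _leaflet_patterns_rejection(
    q: np.ndarray, w: np.ndarray, theta: float, n_leaflets: int, rng: np.random.Generator
) -> np.ndarray:
    """Rejection sampling from the independent proposal (theta >= 0 only)."""
    if theta < 0:
        raise ValueError(
            "aggregation (theta < 0) needs the exact sampler; "
            f"use n_species <= {EXACT_ENUMERATION_MAX_SPECIES}"
        )
    s_n = q.size
    accepted: list[np.ndarray] = []
    attempts = 0
    while len(accepted) < n_leaflets:
        batch = 4 * (n_leaflets - len(accepted)) + 64
        x = (rng.random((batch, s_n)) < q).astype(float)
        pairs_w = 0.5 * np.einsum("bi,ij,bj->b", x, w, x)
        keep = (x.sum(axis=1) >= 1) & (np.log(rng.random(batch)) < -theta * pairs_w)
        attempts += batch
        accepted.extend(x[keep].astype(np.int8))
        if attempts > max(20_000, 2_000 * n_leaflets) and len(accepted) < 0.001 * attempts:
            raise RuntimeError(
                f"rejection rate above 99.9% (theta={theta}, mean q={q.mean():.3f}); "
                "reduce theta or the occupancy probabilities"
            )
    return np.stack(accepted[:n_leaflets])


def simulate_gall_community(cfg: CommunitySimConfig) -> PresenceAbsenceMatrix:
    """Draw one species x leaflet matrix from the pairwise-interaction model.

    Leaflets are independent draws from the weighted-interaction
    distribution conditioned on hosting at least one gall. Communities of
    up to 16 species are sampled exactly (full pattern enumeration); larger
    ones fall back to rejection sampling, which supports segregation and
    independence but not aggregation.
    """
    rng = np.random.default_rng(cfg.seed)
    q = _draw_occupancy(cfg, rng)
    w = pair_competition_weights(q, cfg.competition_weights)
    if cfg.n_species <= EXACT_ENUMERATION_MAX_SPECIES:
        patterns = _leaflet_patterns_exact(q, w, cfg.theta, cfg.n_leaflets, rng)
    else:
        patterns = _leaflet_patterns_rejection(q, w, cfg.theta, cfg.n_leaflets, rng)
    values = patterns.T  # species x leaflets
    n_digits = len(str(cfg.n_leaflets))
    return PresenceAbsenceMatrix(
        site_id=cfg.site_id,
        species_ids=tuple(f"sp{i + 1:02d}" for i in range(cfg.n_species)),
        leaflet_ids=tuple(f"leaf{j + 1:0{n_digits}d}" for j in range(cfg.n_leaflets)),
        values=values,
    )


def simulate_site_environment(
    stress_level: float,
    seed: int = 0,
    noise: float = 1.0,
    site_id: str = "site",
    n_plants: int = 15,
    n_disks_per_plant: int = 10,
) -> tuple[SiteEnvironment, list[LeafDiskRecord]]:
    """Climate, soil and leaf-disk data for one site at the given stress level.

    All planted relations are monotone in stress: AI falls, fertility falls,
    acidity rises, sfm rises. ``noise=0`` gives the exact deterministic
    gradient (useful for construction checks); ``noise=1`` the default
    realistic scatter.
    """
    if not 0.0 <= stress_level <= 1.0:
        raise ValueError("stress_level must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    months = np.arange(24)
    pet = 110.0 + 35.0 * np.sin(2 * np.pi * months / 12.0)
    ai_target = AI_RANGE[0] + (AI_RANGE[1] - AI_RANGE[0]) * stress_level
    precip = ai_target * pet * np.exp(noise * rng.normal(0.0, 0.15, size=24))
    soil = {}
    for var, (fertile, poor) in SOIL_GRADIENT.items():
        value = fertile + (poor - fertile) * stress_level
        value += noise * rng.normal(0.0, 0.04 * abs(poor - fertile))
        soil[var] = max(value, 0.01) if var != "pH" else float(np.clip(value, 3.5, 8.0))
    env = SiteEnvironment(
        site_id=site_id,
        monthly_precip=precip,
        monthly_pet=pet,
        soil_chemistry=pd.Series(soil).reindex(list(SOIL_VARIABLES)),
    )
    sfm_site = SFM_RANGE[0] + (SFM_RANGE[1] - SFM_RANGE[0]) * stress_level
    disks: list[LeafDiskRecord] = []
    for p in range(n_plants):
        sfm_plant = sfm_site + noise * rng.normal(0.0, 1.0)
        for _ in range(n_disks_per_plant):
            sfm_disk = max(sfm_plant + noise * rng.normal(0.0, 0.5), 0.5)
            disks.append(
                LeafDiskRecord(
                    plant_id=f"{site_id}-p{p + 1:02d}",
                    site_id=site_id,
                    disk_dry_mass_mg=sfm_disk * DISK_AREA_CM2,
                )
            )
    return env, disks


@dataclass
class SyntheticSite:
    site_id: str
    stress_level: float
    theta: float
    matrix: PresenceAbsenceMatrix
    environment: SiteEnvironment
    leaf_disks: list[LeafDiskRecord]
    gall_records: list[PlantGallRecord]


@dataclass
class SyntheticStudy:
    """A full simulated gradient dataset plus its ground-truth parameters."""

    sites: list[SyntheticSite]
    ground_truth: dict = field(default_factory=dict)

    @property
    def matrices(self) -> list[PresenceAbsenceMatrix]:
        return [s.matrix for s in self.sites]

    @property
    def environments(self) -> list[SiteEnvironment]:
        return [s.environment for s in self.sites]

    def sfm_means(self) -> dict[str, float]:
        return {
            s.site_id: float(np.mean([d.sfm for d in s.leaf_disks])) for s in self.sites
        }

    def all_gall_records(self) -> list[PlantGallRecord]:
        return [r for s in self.sites for r in s.gall_records]

    def sfm_by_plant(self) -> dict[str, float]:
        out: dict[str, list[float]] = {}
        for s in self.sites:
            for d in s.leaf_disks:
                out.setdefault(d.plant_id, []).append(d.sfm)
        return {k: float(np.mean(v)) for k, v in out.items()}


#: mesic-baseline mean gall richness per plant (crown-level census)
PLANT_RICHNESS_BASE = 4.0


def _simulate_plant_gall_records(
    site_id: str,
    stress_level: float,
    n_plants: int,
    n_species: int,
    rng: np.random.Generator,
    richness_gain: float,
) -> list[PlantGallRecord]:
    """Per-plant crown-census gall records with a planted stress gradient.

    Mean richness rises by a factor ``1 + richness_gain * stress`` from the
    mesic baseline and galls per species also increase with stress.
    Records emulate the whole-crown census (all galls on ten branches),
    which samples far more leaflets than the standardized 137-leaflet
    matrix; they are therefore generated from the planted diversity
    gradient directly rather than read off the matrix — under strong
    segregation the matrix's per-leaflet packing *drops*, while
    crown-level richness in stressed habitats rises with the species pool.
    """
    mean_richness = PLANT_RICHNESS_BASE * (1.0 + richness_gain * stress_level)
    counts_mean = 0.5 + 1.5 * stress_level  # extra galls per species present
    records = []
    for p in range(n_plants):
        richness = int(min(n_species, 1 + rng.poisson(max(mean_richness - 1.0, 0.0))))
        abundance = richness + int(rng.poisson(counts_mean * richness))
        records.append(
            PlantGallRecord(
                plant_id=f"{site_id}-p{p + 1:02d}",
                site_id=site_id,
                richness=richness,
                abundance=abundance,
            )
        )
    return records


def simulate_gradient_study(
    n_sites: int = 7,
    theta_max: float = 1.5,
    n_species: int = 12,
    n_leaflets: int = 137,
    n_plants: int = 15,
    seed: int = 0,
    noise: float = 1.0,
    richness_gain: float = 1.0,
) -> SyntheticStudy:
    """Simulate the full multi-site design: matrices, environments, plants.

    Stress levels are spaced evenly on [0, 1]. Segregation follows a step
    design mirroring the xeric/mesic split: sites in the upper-stress half
    get θ = theta_max, the rest θ = 0. One shared morphospecies pool (one
    occupancy draw) feeds every site's matrix, so observed C-scores are
    comparable across the gradient.

    Plant-level gall records carry the planted diversity gradient: mean
    richness and abundance per plant rise with stress (factor
    ``1 + richness_gain * stress`` on richness). They emulate the
    whole-crown census, a much larger sampling universe than the
    standardized leaflet matrix, and are generated from the planted
    gradient directly (see :func:`_simulate_plant_gall_records`).
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    rng = np.random.default_rng(seed)
    stress_levels = np.linspace(0.0, 1.0, n_sites)
    q_pool = np.exp(rng.uniform(math.log(0.05), math.log(0.4), size=n_species))
    sites: list[SyntheticSite] = []
    for k, stress in enumerate(stress_levels):
        site_id = f"site{k + 1:02d}"
        theta = theta_max if stress > 0.5 else 0.0
        cfg = CommunitySimConfig(
            n_species=n_species,
            n_leaflets=n_leaflets,
            theta=theta,
            base_occupancy=q_pool,
            seed=int(rng.integers(2**31 - 1)),
            site_id=site_id,
        )
        matrix = simulate_gall_community(cfg)
        env, disks = simulate_site_environment(
            stress,
            seed=int(rng.integers(2**31 - 1)),
            noise=noise,
            site_id=site_id,
            n_plants=n_plants,
        )
        galls = _simulate_plant_gall_records(
            site_id, stress, n_plants, n_species, rng, richness_gain
        )
        sites.append(SyntheticSite(site_id, float(stress), theta, matrix, env, disks, galls))
    ground_truth = {
        "theta_by_site": {s.site_id: s.theta for s in sites},
        "stress_by_site": {s.site_id: s.stress_level for s in sites},
        "theta_max": theta_max,
        "ai_range": AI_RANGE,
        "sfm_range_mg_per_cm2": SFM_RANGE,
        "richness_gain": richness_gain,
        "plant_richness_base": PLANT_RICHNESS_BASE,
        "pool_occupancy": q_pool,
    }
    return SyntheticStudy(sites=sites, ground_truth=ground_truth)


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write a study in the CSV dialects the real-data loaders read back.

    Produces one matrix CSV per site plus metadata.csv, climate.csv,
    soil.csv, leaf.csv and galls.csv under ``outdir``.
    """
    from .matrix import write_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta, climate, soil, leaf, galls = [], [], [], [], []
    for s in study.sites:
        matrix_path = outdir / f"matrix_{s.site_id}.csv"
        write_matrix(s.matrix, matrix_path)
        meta.append(
            {
                "site_id": s.site_id,
                "habitat": f"stress={s.stress_level:.2f}",
                "matrix_file": matrix_path.name,
                "theta_true": s.theta,
            }
        )
        env = s.environment
        for month, (p, pet) in enumerate(zip(env.monthly_precip, env.monthly_pet), start=1):
            climate.append(
                {"site_id": s.site_id, "month": month, "precip_mm": p, "pet_mm": pet}
            )
        soil.append({"site_id": s.site_id, **env.soil_chemistry.to_dict()})
        for d in s.leaf_disks:
            leaf.append(
                {
                    "plant_id": d.plant_id,
                    "site_id": d.site_id,
                    "disk_dry_mass_mg": d.disk_dry_mass_mg,
                    "disk_area_cm2": d.disk_area_cm2,
                }
            )
        for g in s.gall_records:
            galls.append(
                {
                    "plant_id": g.plant_id,
                    "site_id": g.site_id,
                    "richness": g.richness,
                    "abundance": g.abundance,
                }
            )
    pd.DataFrame(meta).to_csv(outdir / "metadata.csv", index=False)
    pd.DataFrame(climate).to_csv(outdir / "climate.csv", index=False)
    pd.DataFrame(soil).to_csv(outdir / "soil.csv", index=False)
    pd.DataFrame(leaf).to_csv(outdir / "leaf.csv", index=False)
    pd.DataFrame(galls).to_csv(outdir / "galls.csv", index=False)
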