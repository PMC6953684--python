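"""Environmental-stress indicators and the gradient regression stages.

Three site-level stress indicators are computed and then regressed against
the co-occurrence effect size (NES C-score):

* aridity index AI = P/PET averaged over 24 monthly ratios (lower = more
  arid);
* specific leaf mass sfm = leaf-disk dry mass / disk area (mg/cm^2), a
  sclerophylly proxy, averaged per site;
* the first axis of a correlation-matrix PCA of 11 soil-chemistry
  variables, oriented so that base saturation (V) loads positively
  (fertile sites score high).

Diversity stages: per-plant gall richness/abundance vs site (Poisson GLM
with quasi-Poisson dispersion correction when needed) and vs sfm (Poisson
mixed model with a random site intercept, tested by likelihood ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import fit_poisson_glmm, likelihood_ratio_test

__all__ = [
    "SOIL_VARIABLES",
    "DISK_AREA_CM2",
    "SiteEnvironment",
    "LeafDiskRecord",
    "PlantGallRecord",
    "ModelFit",
    "SoilPCA",
    "aridity_index",
    "specific_leaf_mass",
    "soil_pca",
    "attach_soil_pc1",
    "fit_gaussian_glm",
    "fit_stress_models",
    "fit_diversity_models",
    "fit_trait_mixed_model",
    "load_climate_csv",
    "load_soil_csv",
    "load_leaf_csv",
    "load_gall_csv",
]

#: soil fertility/acidity variables entering the PCA, in canonical order
SOIL_VARIABLES = ("pH", "H+Al", "Al3+", "Ca", "Mg", "P", "K", "SB", "t", "m", "V")

#: leaf-disk punch area, cm^2
DISK_AREA_CM2 = 0.38

#: Pearson dispersion above which the Poisson GLM switches to quasi-Poisson
QUASI_POISSON_DISPERSION = 1.5


@dataclass
class SiteEnvironment:
    """Climate series, soil chemistry and derived stress scores for one site."""

    site_id: str
    monthly_precip: np.ndarray  # mm, 24 months
    monthly_pet: np.ndarray  # mm, 24 months
    soil_chemistry: pd.Series  # indexed by SOIL_VARIABLES
    soil_pc1: float | None = None  # filled in after the cross-site PCA

    def __post_init__(self) -> None:
        self.monthly_precip = np.asarray(self.monthly_precip, dtype=float)
        self.monthly_pet = np.asarray(self.monthly_pet, dtype=float)
        if self.monthly_precip.shape != self.monthly_pet.shape:
            raise ValueError("precipitation and PET series differ in length")

    @property
    def aridity_index(self) -> float:
        return aridity_index(self)


@dataclass(frozen=True)
class LeafDiskRecord:
    """One dried leaf disk; sfm is its dry mass per unit punch area."""

    plant_id: str
    site_id: str
    disk_dry_mass_mg: float
    disk_area_cm2: float = DISK_AREA_CM2

    def __post_init__(self) -> None:
        if self.disk_dry_mass_mg < 0:
            raise ValueError("disk dry mass cannot be negative")
        if self.disk_area_cm2 <= 0:
            raise ValueError("disk area must be positive")

    @property
    def sfm(self) -> float:
        return self.disk_dry_mass_mg / self.disk_area_cm2


@dataclass(frozen=True)
class PlantGallRecord:
    """Gall morphospecies richness and gall abundance on one plant."""

    plant_id: str
    site_id: str
    richness: int
    abundance: int

    def __post_init__(self) -> None:
        if not (0 <= self.richness <= self.abundance):
            raise ValueError("need 0 <= richness <= abundance")


@dataclass(frozen=True)
class ModelFit:
    """A fitted regression stage and its deviance-analysis test."""

    label: str
    coefficients: dict
    deviance: float  # deviance explained by the term of interest
    residual_deviance: float
    df: tuple[int, int]  # (df of the term, residual df)
    statistic_name: str  # "F" or "chi2"
    statistic: float
    p_value: float
    family: str = "gaussian"
    dispersion: float | None = None


# ---------------------------------------------------------------------------
# indicators


def aridity_index(env, method: str = "monthly_mean") -> float:
    """AI from paired monthly precipitation/PET series.

    ``monthly_mean`` (default) averages the 24 monthly P/PET ratios;
    ``totals`` uses sum(P)/sum(PET). Lower AI = more arid. Strictly
    decreasing in any PET increase and homogeneous of degree 1 in P.
    """
    if isinstance(env, SiteEnvironment):
        p, pet = env.monthly_precip, env.monthly_pet
    else:
        p, pet = (np.asarray(x, dtype=float) for x in env)
    if p.shape != pet.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("need equal-length, non-empty monthly series")
    missing = np.flatnonzero(np.isnan(p) | np.isnan(pet))
    if missing.size:
        raise ValueError(f"missing monthly values at positions {missing.tolist()}")
    if (pet <= 0).any():
        raise ValueError("PET must be positive for every month")
    if method == "monthly_mean":
        return float(np.mean(p / pet))
    if method == "totals":
        return float(p.sum() / pet.sum())
    raise ValueError(f"unknown AI aggregation {method!r}")


def specific_leaf_mass(disk_dry_mass_mg, disk_area_cm2: float = DISK_AREA_CM2):
    """sfm = disk dry mass / disk area, in mg/cm^2."""
    if isinstance(disk_dry_mass_mg, LeafDiskRecord):
        return disk_dry_mass_mg.sfm
    mass = np.asarray(disk_dry_mass_mg, dtype=float)
    if (mass < 0).any():
        raise ValueError("disk dry mass cannot be negative")
    if disk_area_cm2 <= 0:
        raise ValueError("disk area must be positive")
    out = mass / disk_area_cm2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SoilPCA:
    scores: pd.DataFrame  # sites x components
    loadings: pd.DataFrame  # variables x components (unit-norm columns)
    variance_fractions: np.ndarray


def soil_pca(table: pd.DataFrame) -> SoilPCA:
    """Correlation-matrix PCA of the site x soil-chemistry table.

    Variables are standardized to zero mean and unit variance (ddof=1, the
    prcomp(scale=TRUE) convention) before the SVD, so each soil variable
    contributes equally regardless of units. PC1 is oriented so base
    saturation V — or, if V is absent, the variable with the largest
    absolute loading — loads positively: fertile sites score high.
    """
    if table.shape[0] < 3:
        raise ValueError("soil PCA needs at least 3 sites")
    if table.isna().any().any():
        raise ValueError("soil table contains missing values")
    x = table.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        name = table.columns[int(np.argmax(sd == 0))]
        raise ValueError(f"soil variable {name!r} is constant across sites")
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u * s
    loadings = vt.T
    # deterministic sign: orient every axis by its largest-|loading| variable
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    if "V" in table.columns:
        jv = list(table.columns).index("V")
        if loadings[jv, 0] < 0:
            loadings[:, 0] *= -1
            scores[:, 0] *= -1
    var = s**2
    comps = [f"PC{k + 1}" for k in range(len(s))]
    return SoilPCA(
        scores=pd.DataFrame(scores, index=table.index, columns=comps),
        loadings=pd.DataFrame(loadings, index=table.columns, columns=comps),
        variance_fractions=var / var.sum(),
    )


def attach_soil_pc1(envs: Sequence[SiteEnvironment]) -> SoilPCA:
    """Run the cross-site soil PCA and store each site's PC1 score in place."""
    table = pd.DataFrame(
        {e.site_id: e.soil_chemistry.reindex(SOIL_VARIABLES) for e in envs}
    ).T
    pca = soil_pca(table)
    for e in envs:
        e.soil_pc1 = float(pca.scores.loc[e.site_id, "PC1"])
    return pca


# ---------------------------------------------------------------------------
# regression stages


def fit_gaussian_glm(y, x, label: str = "gaussian") -> ModelFit:
    """Simple Gaussian regression y ~ x with a deviance-analysis F test."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size:
        raise ValueError("response and explanatory variable differ in length")
    if y.size < 3:
        raise ValueError("need at least 3 sites to fit the model")
    if np.ptp(x) == 0:
        raise ValueError("explanatory variable is constant: slope unidentifiable")
    X = sm.add_constant(x)
    fit = sm.GLM(y, X, family=sm.families.Gaussian()).fit()
    null = sm.GLM(y, np.ones_like(y), family=sm.families.Gaussian()).fit()
    dev_term = null.deviance - fit.deviance
    df_resid = int(fit.df_resid)
    if fit.deviance <= 0 or df_resid == 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (dev_term / 1.0) / (fit.deviance / df_resid)
        p = float(stats.f.sf(f_stat, 1, df_resid))
    return ModelFit(
        label=label,
        coefficients={"intercept": float(fit.params[0]), "slope": float(fit.params[1])},
        deviance=float(dev_term),
        residual_deviance=float(fit.deviance),
        df=(1, df_resid),
        statistic_name="F",
        statistic=float(f_stat),
        p_value=p,
        family="gaussian",
    )


def fit_stress_models(
    results,
    envs: Sequence[SiteEnvironment],
    sfm_means: Mapping[str, float],
    effect: str = "nes",
) -> dict[str, ModelFit]:
    """Site-level regressions of the co-occurrence effect size on stress.

    ``results`` are per-site co-occurrence records (anything with
    ``site_id`` and the chosen ``effect`` attribute); ``envs`` supply AI
    and soil PC1 (run :func:`attach_soil_pc1` first); ``sfm_means`` map
    site to mean specific leaf mass. One Gaussian fit per indicator in
    {sfm, aridity, soil_pc1}; slope signs are exposed in the coefficients.
    """
    env_by_site = {e.site_id: e for e in envs}
    sites = [r.site_id for r in results]
    missing = [s for s in sites if s not in env_by_site or s not in sfm_means]
    if missing:
        raise ValueError(f"missing environment or sfm for sites {missing}")
    if any(env_by_site[s].soil_pc1 is None for s in sites):
        raise ValueError("soil PC1 not computed; call attach_soil_pc1 first")
    y = np.array([getattr(r, effect) for r in results], dtype=float)
    indicators = {
        "sfm": np.array([sfm_means[s] for s in sites], dtype=float),
        "aridity": np.array([env_by_site[s].aridity_index for s in sites]),
        "soil_pc1": np.array([env_by_site[s].soil_pc1 for s in sites], dtype=float),
    }
    return {
        name: fit_gaussian_glm(y, x, label=f"{effect} ~ {name}")
        for name, x in indicators.items()
    }


def _records_frame(records: Iterable[PlantGallRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"plant_id": r.plant_id, "site_id": r.site_id,
             "richness": r.richness, "abundance": r.abundance}
            for r in records
        ]
    )
    if df.empty:
        raise ValueError("no plant gall records")
    return df


def fit_diversity_models(
    records: Iterable[PlantGallRecord],
    responses: Sequence[str] = ("richness", "abundance"),
) -> dict[str, ModelFit]:
    """Per-plant gall counts vs site: Poisson GLM with ANODEV.

    The site term is tested by deviance analysis; when the Pearson
    dispersion of the site model exceeds 1.5 the fit is treated as
    quasi-Poisson (deviance F test scaled by the dispersion), otherwise a
    likelihood-ratio chi-square is reported.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = _records_frame(records)
    counts = df.groupby("site_id")["plant_id"].count()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 sites with >= 2 plants each")
    out: dict[str, ModelFit] = {}
    for resp in responses:
        if (df[resp] == 0).all():
            raise ValueError(f"all-zero response {resp!r}")
        fit = smf.glm(f"{resp} ~ C(site_id)", data=df, family=sm.families.Poisson()).fit()
        null = smf.glm(f"{resp} ~ 1", data=df, family=sm.families.Poisson()).fit()
        df_term = int(null.df_resid - fit.df_resid)
        df_resid = int(fit.df_resid)
        dev_term = float(null.deviance - fit.deviance)
        dispersion = float(fit.pearson_chi2 / df_resid)
        if dispersion > QUASI_POISSON_DISPERSION:
            f_stat = (dev_term / df_term) / dispersion
            p = float(stats.f.sf(f_stat, df_term, df_resid))
            stat_name, stat, family = "F", float(f_stat), "quasipoisson"
        else:
            stat_name, stat, family = "chi2", dev_term, "poisson"
            p = float(stats.chi2.sf(dev_term, df_term))
        out[resp] = ModelFit(
            label=f"{resp} ~ site",
            coefficients={k: float(v) for k, v in fit.params.items()},
            deviance=dev_term,
            residual_deviance=float(fit.deviance),
            df=(df_term, df_resid),
            statistic_name=stat_name,
            statistic=stat,
            p_value=p,
            family=family,
            dispersion=dispersion,
        )
    return out


def fit_trait_mixed_model(
    records: Iterable[PlantGallRecord],
    sfm_by_plant: Mapping[str, float],
    response: str = "richness",
) -> ModelFit:
    """Per-plant gall counts vs sfm with a random site intercept.

    Poisson mixed model fit by maximum likelihood (Gauss-Hermite
    quadrature); the sfm slope is tested by likelihood-ratio chi-square
    against the intercept-plus-random-effect null.
    """
    df = _records_frame(records)
    if df["site_id"].nunique() < 2:
        raise ValueError("random site effect unidentifiable with a single site")
    missing = [p for p in df["plant_id"] if p not in sfm_by_plant]
    if missing:
        raise ValueError(f"missing sfm for plants {missing[:5]}")
    y = df[response].to_numpy(dtype=float)
    sfm = np.array([sfm_by_plant[p] for p in df["plant_id"]], dtype=float)
    sfm_c = sfm - sfm.mean()  # centering stabilizes the quadrature
    groups = df["site_id"].to_numpy()
    X_full = np.column_stack([np.ones_like(sfm_c), sfm_c])
    X_null = np.ones((len(y), 1))
    null = fit_poisson_glmm(y, X_null, groups, exog_names=("intercept",))
    full = fit_poisson_glmm(y, X_full, groups, exog_names=("intercept", "sfm"))
    if full.loglik < null.loglik:  # restart from the null optimum
        full = fit_poisson_glmm(y, X_full, groups, exog_names=("intercept", "sfm"))
    lr, p, df_term = likelihood_ratio_test(full, null)
    return ModelFit(
        label=f"{response} ~ sfm + (1|site)",
        coefficients={
            "intercept": float(full.beta[0]),
            "sfm": float(full.beta[1]),
            "sigma_site": full.sigma,
        },
        deviance=lr,
        residual_deviance=float(-2.0 * full.loglik),
        df=(df_term, full.n_obs - 3),
        statistic_name="chi2",
        statistic=lr,
        p_value=p,
        family="poisson_glmm",
    )


# ---------------------------------------------------------------------------
# field-data loaders (one CSV dialect per input table)


def load_climate_csv(path) -> dict[str, SiteEnvironment]:
    """Climate CSV: site_id, month, precip_mm, pet_mm (soil attached separately)."""
    df = pd.read_csv(Path(path))
    required = {"site_id", "month", "precip_mm", "pet_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"climate table needs columns {sorted(required)}")
    envs: dict[str, SiteEnvironment] = {}
    for site, grp in df.groupby("site_id", sort=False):
        grp = grp.sort_values("month")
        envs[str(site)] = SiteEnvironment(
            site_id=str(site),
            monthly_precip=grp["precip_mm"].to_numpy(),
            monthly_pet=grp["pet_mm"].to_numpy(),
            soil_chemistry=pd.Series(np.nan, index=list(SOIL_VARIABLES)),
        )
    return envs


def load_soil_csv(path) -> pd.DataFrame:
    """Soil CSV: one row per site_id, one column per soil variable."""
    df = pd.read_csv(Path(path), index_col="site_id")
    missing = [v for v in SOIL_VARIABLES if v not in df.columns]
    if missing:
        raise ValueError(f"soil table missing variables {missing}")
    return df[list(SOIL_VARIABLES)]


def load_leaf_csv(path) -> list[LeafDiskRecord]:
    """Leaf CSV: plant_id, site_id, disk_dry_mass_mg [, disk_area_cm2]."""
    df = pd.read_csv(Path(path))
    area = "disk_area_cm2" in df.columns
    return [
        LeafDiskRecord(
            plant_id=str(r.plant_id),
            site_id=str(r.site_id),
            disk_dry_mass_mg=float(r.disk_dry_mass_mg),
            disk_area_cm2=float(r.disk_area_cm2) if area else DISK_AREA_CM2,
        )
        for r in df.itertuples()
    ]


def load_gall_csv(path) -> list[PlantGallRecord]:
    """Gall CSV: plant_id, site_id, richness, abundance."""
    df = pd.read_csv(Path(path))
    return [
        PlantGallRecord(
            plant_id=str(r.plant_id),
            site_id=str(r.site_id),
            richness=int(r.richness),
            abundance=int(r.abundance),
        )
        for r in df.itertuples()
    ]
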