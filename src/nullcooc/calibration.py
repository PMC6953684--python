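"""Calibration and power studies of the co-occurrence pipeline.

These routines validate the machinery on communities with known structure:
type-I error at the exact θ = 0 null, power and NES recovery under planted
segregation, agreement of the swap sampler with the exhaustive enumeration
oracle, margin conservation, and sign recovery of the stress-gradient
regressions. They are the same computations the package's acceptance
checks run; exposing them lets users re-verify calibration under their own
designs.

Replicated studies use deliberately reduced chain settings (1,000 null
matrices, thinning of roughly 1-2 thousand attempted swaps) so that
hundreds of replicates fit in minutes; single-site analyses keep the full
defaults (5,000 nulls, thinning 10·R·C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cscore import c_score
from .inference import RunConfig, analyze_site
from .matrix import PresenceAbsenceMatrix, drop_empty_species, filter_galled_leaflets
from .null_model import enumerate_fixed_margin_matrices, generate_null_ensemble
from .pipeline import analyze_gradient_study
from .synthetic import CommunitySimConfig, simulate_gall_community, simulate_gradient_study

__all__ = [
    "replication_run_config",
    "type_i_error_rate",
    "segregation_recovery",
    "SamplerOracleComparison",
    "compare_sampler_to_oracle",
    "count_margin_violations",
    "gradient_sign_rates",
]


def replication_run_config(seed: int = 0, n_null: int = 1_000) -> RunConfig:
    """Reduced chain settings used for replicated simulation studies."""
    return RunConfig(n_null=n_null, burn_in=10_000, thin=2_000, seed=seed)


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n + 1, np.uint32)[1:] % (2**31 - 1)


def type_i_error_rate(
    n_rep: int = 500,
    n_species: int = 10,
    n_leaflets: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Segregation rejection fraction on θ = 0 communities.

    At θ = 0 species are independent given non-emptiness, and conditional
    on both margins the matrix is exactly uniform over the fixed-margin
    set, so the nominal level should be attained up to the discreteness of
    the permutation p-value.
    """
    seeds = _rep_seeds(seed, n_rep)
    config = RunConfig(n_null=1_000, burn_in=5_000, thin=1_000, seed=seed)
    rejections = 0
    for rep in range(n_rep):
        cfg = CommunitySimConfig(
            n_species=n_species, n_leaflets=n_leaflets, theta=0.0,
            seed=int(seeds[rep]), site_id=f"null{rep}",
        )
        m = drop_empty_species(filter_galled_leaflets(simulate_gall_community(cfg)))
        result = analyze_site(m, config)
        rejections += result.p_ge <= alpha
    return rejections / n_rep


@dataclass
class SegregationRecovery:
    theta: float
    power: float  # fraction of replicates with p_ge <= alpha
    nes_positive_rate: float
    median_nes: float
    n_rep: int


def segregation_recovery(
    theta: float,
    n_rep: int = 100,
    n_species: int = 12,
    n_leaflets: int = 137,
    alpha: float = 0.05,
    seed: int = 0,
) -> SegregationRecovery:
    """Detection rate and NES distribution under planted segregation θ."""
    seeds = _rep_seeds(seed, n_rep)
    config = replication_run_config(seed)
    rejections = nes_positive = 0
    nes_values = []
    for rep in range(n_rep):
        cfg = CommunitySimConfig(
            n_species=n_species, n_leaflets=n_leaflets, theta=theta,
            seed=int(seeds[rep]), site_id=f"theta{theta}-{rep}",
        )
        m = drop_empty_species(filter_galled_leaflets(simulate_gall_community(cfg)))
        result = analyze_site(m, config)
        rejections += result.p_ge <= alpha
        nes_positive += result.nes > 0
        nes_values.append(result.nes)
    return SegregationRecovery(
        theta=theta,
        power=rejections / n_rep,
        nes_positive_rate=nes_positive / n_rep,
        median_nes=float(np.median(nes_values)),
        n_rep=n_rep,
    )


@dataclass
class SamplerOracleComparison:
    n_matrices: int  # size K of the fixed-margin family
    n_samples: int
    total_variation: float  # TV distance between sampled and uniform
    chi2_p_value: float  # GOF against the uniform distribution


def compare_sampler_to_oracle(
    row_totals,
    col_totals,
    n_samples: int = 50_000,
    thin: int = 1_000,
    seed: int = 0,
) -> SamplerOracleComparison:
    """Sampled matrix frequencies vs the exact uniform fixed-margin law.

    Every matrix with the given margins is enumerated; the swap chain is
    then run and each sample is identified (bit-packed) with one of the
    enumerated matrices. A uniform sampler should give total-variation
    distance near zero and a non-significant chi-square GOF.
    """
    mats = enumerate_fixed_margin_matrices(row_totals, col_totals)
    if not mats:
        raise ValueError("infeasible margins")
    n_rows, n_cols = mats[0].shape
    if n_rows * n_cols > 52:
        raise ValueError("matrix too large to identify samples by bit code")
    powers = 2 ** np.arange(n_rows * n_cols, dtype=np.int64)

    def code(a: np.ndarray) -> float:
        return float(a.reshape(-1).astype(np.int64) @ powers)

    index = {code(a): i for i, a in enumerate(mats)}
    start = PresenceAbsenceMatrix(
        "oracle",
        tuple(f"r{i}" for i in range(n_rows)),
        tuple(f"c{j}" for j in range(n_cols)),
        mats[0],
    )
    ensemble = generate_null_ensemble(
        start, statistic=code, n=n_samples, burn_in=10 * thin, thin=thin, seed=seed
    )
    counts = np.zeros(len(mats), dtype=np.int64)
    for v in ensemble.values:
        counts[index[v]] += 1
    expected = n_samples / len(mats)
    tv = 0.5 * float(np.abs(counts / n_samples - 1.0 / len(mats)).sum())
    chi2_p = float(stats.chisquare(counts, f_exp=expected).pvalue)
    return SamplerOracleComparison(len(mats), n_samples, tv, chi2_p)


def count_margin_violations(
    m: PresenceAbsenceMatrix, n: int = 5_000, seed: int = 0, thin: int | None = None
) -> int:
    """Number of sampled null matrices whose margins differ from the source."""
    row_t = m.row_totals
    col_t = m.col_totals
    violations = 0

    def check(mat: np.ndarray) -> float:
        nonlocal violations
        if not (
            np.array_equal(mat.sum(axis=1), row_t) and np.array_equal(mat.sum(axis=0), col_t)
        ):
            violations += 1
        return 0.0

    generate_null_ensemble(m, statistic=check, n=n, thin=thin, seed=seed)
    return violations


@dataclass
class GradientSignRates:
    sfm_positive: float
    aridity_negative: float
    soil_pc1_negative: float  # ground-truth direction: fertility falls with stress
    xeric_detection_rate: float
    mesic_rejection_rate: float
    n_rep: int


def gradient_sign_rates(
    n_rep: int = 100, theta_max: float = 1.5, alpha: float = 0.05, seed: int = 0
) -> GradientSignRates:
    """Sign recovery of the NES-vs-stress regressions on simulated gradients.

    Planted truth: segregation (θ = theta_max) in the xeric half, none in
    the mesic half; sfm rises and both AI and soil fertility fall with
    stress. NES should therefore regress positively on sfm and negatively
    on both AI and soil PC1.
    """
    seeds = _rep_seeds(seed, n_rep)
    sfm_pos = ai_neg = pc1_neg = 0
    xeric_hits = xeric_n = mesic_hits = mesic_n = 0
    for rep in range(n_rep):
        study = simulate_gradient_study(theta_max=theta_max, seed=int(seeds[rep]))
        config = replication_run_config(seed=int(seeds[rep]), n_null=500)
        gr = analyze_gradient_study(study, config)
        slopes = {k: f.coefficients["slope"] for k, f in gr.stress_fits.items()}
        sfm_pos += slopes["sfm"] > 0
        ai_neg += slopes["aridity"] < 0
        pc1_neg += slopes["soil_pc1"] < 0
        theta_by_site = study.ground_truth["theta_by_site"]
        for r in gr.cooc_results:
            if theta_by_site[r.site_id] > 0:
                xeric_n += 1
                xeric_hits += r.p_ge <= alpha
            else:
                mesic_n += 1
                mesic_hits += r.p_ge <= alpha
    return GradientSignRates(
        sfm_positive=sfm_pos / n_rep,
        aridity_negative=ai_neg / n_rep,
        soil_pc1_negative=pc1_neg / n_rep,
        xeric_detection_rate=xeric_hits / xeric_n,
        mesic_rejection_rate=mesic_hits / mesic_n,
        n_rep=n_rep,
    )
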