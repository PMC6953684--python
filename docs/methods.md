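# Methods

This note documents the statistical machinery, the synthetic-data model,
the numerical choices, and the known limitations of `nullcooc`.

## Co-occurrence statistic and null model

The unit of analysis is a binary species × leaflet matrix per site,
species on rows. For each unordered species pair, checkerboard units are
`CU = (r_i − S)(r_j − S)` where `r` are row totals and `S` the number of
leaflets shared; the C-score is the mean CU over all `R(R−1)/2` pairs.
Species absent from the analysed leaflet set are dropped before the
statistic is computed (an absent species contributes only degenerate
`CU = 0` pairs, which would dilute the mean); all-zero leaflets are
removed by the galled-leaflet filter, which the sampling design makes a
no-op on clean data.

The null hypothesis fixes both margins and puts uniform probability on
every binary matrix with those margins. Sampling uses a swap chain:

* each attempt draws two rows and two columns uniformly *with
  replacement*; if the four indices are distinct and the induced 2×2
  submatrix is a checkerboard, it is flipped. Repeated indices are lazy
  moves. The proposal is symmetric and the acceptance deterministic, so
  the stationary law is uniform; laziness makes the chain aperiodic on
  every margin family (a 2×2 checkerboard matrix would otherwise
  oscillate with period 2).
* thinning counts **attempted** swaps (default `thin = max(1000,
  10·R·C)`, burn-in 30,000 attempts). Counting accepted swaps instead —
  the classic sequential-swap convention — biases sampling toward
  matrices with many checkerboards; it is retained as
  `thin_unit="swaps"` for comparisons with legacy software but is not
  the default.
* a matrix accepting no swap during burn-in is *rigid*: the ensemble is
  flagged degenerate and inference reports `p = 1`, `NES = SES = 0` with
  a warning rather than failing a multi-site run.

Correctness is established against an exhaustive oracle: a column-wise
backtracking enumeration of all fixed-margin matrices with Gale–Ryser
feasibility pruning (guarded at 10⁶ partial states). On enumerable
families the sampled matrix frequencies match the uniform law
(total-variation distance ≲ 0.02 at 50,000 samples; chi-square GOF
non-significant), and sampled tail probabilities match exact ones within
Monte-Carlo error.

Inference reports both one-tailed permutation p-values with the add-one
correction `p = (1 + k)/(n + 1)` (ties count in both tails, so
`p_ge + p_le ≥ 1` and `p ≥ 1/(n+1)`; at n = 5,000 the smallest
attainable p prints as .0002). Two effect sizes are always carried:
`NES = (obs − mean)/mean`, the normalized effect size the gradient
regressions use, and the classical `SES = (obs − mean)/sd` (undefined and
reported as missing when the null sd is 0). Reporting both resolves the
ambiguity between the two conventions at no cost. No multiple-testing
correction is applied across sites.

Reproducibility: one master seed; each site derives its own stream by
hashing the site label (CRC-32 into a seed sequence), so multi-site
results do not depend on analysis order. The chain's inner loop is
numba-compiled; per-segment kernel seeds come from the site stream.

## Stress indicators

* **Aridity index**: `AI = mean over 24 months of (P_m / PET_m)`; the
  alternative aggregation `ΣP/ΣPET` is exposed as an option
  (`method="totals"`). The monthly-mean form is the default because the
  underlying index is defined as a monthly ratio; averaging preserves it.
  Errors on missing months or non-positive PET.
* **Specific leaf mass**: disk dry mass (mg) / disk area (0.38 cm²
  default), i.e. mg/cm²; site-level analyses use the mean over a site's
  plants.
* **Soil PCA**: variables standardized to zero mean, unit variance
  (ddof = 1; the `prcomp(scale=TRUE)` convention), then SVD. Axes are
  sign-fixed deterministically (largest-|loading| variable positive) and
  PC1 is re-oriented so base saturation V loads positively: fertile sites
  score high. Constant variables raise an error naming the variable.

## Regression stages

* **NES ~ indicator** (one per indicator: sfm mean, AI, soil PC1):
  Gaussian GLM on *site-level* values (the gradient design has one NES
  per site), tested by deviance-analysis F with the degrees of freedom of
  the actual design — for 7 sites, `F(1, 5)`. With fewer than 3 sites the
  model is unidentifiable and errors.
* **richness/abundance ~ site**: per-plant Poisson GLM with deviance
  analysis; when the Pearson dispersion of the site model exceeds 1.5 the
  fit switches to quasi-Poisson (deviance F scaled by the dispersion),
  otherwise a likelihood-ratio chi-square is reported. The 1.5 threshold
  operationalizes "correct for overdispersion when necessary".
* **richness/abundance ~ sfm + (1 | site)**: Poisson mixed model with a
  random site intercept, fit by *maximum likelihood* using non-adaptive
  Gauss–Hermite quadrature (25 nodes) over the random effect and
  L-BFGS-B over (β, σ), σ bounded in [1e-8, 10]; the slope is tested by
  likelihood-ratio chi-square against the intercept-plus-random-effect
  null, with the statistic clamped at 0 against optimizer round-off and
  the full fit started from the null optimum so nesting is respected
  numerically. The fitter agrees with `lme4::glmer` (nAGQ = 25) to ~1e-3
  on coefficients and ~0.01 on the LR statistic (cross-checked in the
  test suite). Non-adaptive quadrature is adequate here because group
  counts are moderate and σ is small; very large per-group information
  with large σ would call for adaptive quadrature.

## Synthetic-data generator

**Community model.** Each leaflet's occupancy pattern `x ∈ {0,1}^S` is an
independent draw from the pairwise-interaction family

    P(x) ∝ exp( Σ_s x_s·logit(q_s) − θ·Σ_{s<t} w_st·x_s·x_t ),

conditioned on `Σ x ≥ 1` (only galled leaflets enter the matrix).
Per-species occupancy `q_s` is log-uniform on [0.05, 0.4] by default,
mimicking the right-skewed occupancy of gall morphospecies. θ = 0 gives
exact independence given non-emptiness — and because the conditional law
given both margins is then exactly uniform, θ = 0 is a *true null* for
the fixed-fixed test, which is what makes the type-I calibration target
meaningful. Sampling is exact: for ≤ 16 species all `2^S − 1` non-empty
patterns are enumerated and drawn directly; larger communities use
rejection sampling from the independent proposal (θ ≥ 0 only; errors if
the rejection rate exceeds 99.9%).

**Why the pair weights are not uniform.** With `w_st ≡ 1` the
interaction term equals `θ·Σ_j c_j(c_j−1)/2` — a function of the column
totals alone — so conditional on the margins the matrix is uniform for
*any* θ and a fixed-fixed test has exactly zero power against it. Worse,
`Σ_pairs S_st` is itself fixed by the column totals, so even pair-specific
structure *uncorrelated with abundance* cancels at first order in the
C-score (a Bernoulli competition graph yields only curvature-level
signal). The default is therefore **encounter-rate weights**
`w_st = q_s·q_t / mean(q)²`: interference competition is strongest
between abundant, frequently-encountering morphospecies, and θ reads as
the co-occurrence penalty for an average-abundance pair. Shifting shared
leaflets away from abundant pairs (steep CU slope) toward rare pairs
(shallow slope) produces first-order C-score signal; at θ = 1.5 the
pipeline detects segregation in ≈ 90–95% of 12 × 137 communities. The
`competition_weights="uniform"` option retains the margin-absorbed
variant for demonstrating the degeneracy.

**Aggregation caveat.** Under abundance-weighted *attraction* (θ < 0)
abundant species saturate toward full occupancy and the effect is largely
absorbed by the margins: the C-score's NES does not reliably go negative.
The aggregation regime is supported (exact sampler) but sign recovery is
only claimed for segregation.

**Gradient studies.** Stress levels are evenly spaced on [0, 1] across
`n_sites` (default 7). Planted relations, all monotone in stress with
Gaussian noise (`noise=0` gives the exact deterministic gradient):

| quantity | mesic (stress 0) | xeric (stress 1) |
|---|---|---|
| aridity index target | 1.3 | 0.3 |
| site-mean sfm (mg/cm²) | 8 | 15 |
| soil fertility (pH, Ca, Mg, P, K, SB, t, V) | high | low |
| soil acidity (H+Al, Al3+, m) | low | high |
| θ (step at stress 0.5) | 0 | `theta_max` |
| mean plant richness | 4 | 4·(1 + `richness_gain`) |

PET is a 24-month seasonal sinusoid (110 ± 35 mm); precipitation is
`AI_target · PET` with multiplicative log-normal noise. One shared
species pool (one occupancy draw) feeds all sites so C-scores are
comparable along the gradient.

**Plant-level gall records** emulate the whole-crown census — a far
larger sampling universe than the standardized 137-leaflet matrix — and
are drawn from the planted diversity gradient directly (per-plant
richness `1 + Poisson`, capped at the pool size; abundance = richness +
`Poisson(richness·(0.5 + 1.5·stress))`). They are deliberately *not*
derived by partitioning the matrix: under strong segregation per-leaflet
packing necessarily thins (in the θ → ∞ limit every leaflet hosts a
single species), so a matrix partition cannot simultaneously carry a
rising richness gradient and a segregation step. Consequence: the
diversity stages and the co-occurrence stages are statistically
decoupled in simulated studies — passing tests show each stage works on
its planted signal, not that matrix and census covary as in real data.

**What the generator does not emulate:** gall phenology, parasitoid
(top-down) dynamics, plant architecture, spatial autocorrelation among
leaflets within branches or plants, and any matrix–census coupling.
Calibration and power results transfer to field data only insofar as the
fixed-fixed null (exchangeability of leaflets given margins) is the right
conditioning there.

## Simulation sizes and numerical choices

Replicated studies use reduced chain settings — 1,000 null matrices,
burn-in 5,000–10,000 attempts, thinning 1,000–2,000 attempts (and 500
nulls inside the 100-replicate gradient studies) — chosen so hundreds of
replicates complete in minutes while p-value resolution (≥ 1/1001)
remains fine for tests at α = 0.05. Single-site analyses default to the
full 5,000 nulls with thinning 10·R·C. The NES-median monotonicity check
across θ ∈ {0, 0.5, 1, 1.5} uses 300 replicates per θ because the median
saturates between θ = 1.0 and 1.5 and 100 replicates cannot resolve the
ordering. Statistic values are exact integer arithmetic rendered in
floating point; exact-distribution keys are rounded to 9 decimals to pool
numerically identical values. Enumeration refuses inputs beyond 10⁶
partial states and points to the sampler.

## Known limitations

* The swap chain is uniform by construction (attempt-counted thinning);
  the legacy acceptance-counted mode is provided for comparability but is
  knowingly non-uniform on heterogeneous margin families.
* Serial correlation between consecutive null samples is controlled by
  thinning, not eliminated; permutation p-values remain valid because the
  chain starts at the observed matrix, but very short thinning would
  reduce effective ensemble size.
* NES is undefined for null mean 0 and SES for null sd 0 (rigid
  families); degenerate results are flagged, not dropped.
* Real soil chemistry is correlated and partly compositional (SB, t, m
  and V are functions of the cations); the generator only mimics this
  with independent Gaussian noise around monotone trends, so simulated
  soil PC1 is cleaner than field PC1.
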