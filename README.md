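# nullcooc

Null-model co-occurrence analysis for gall-inducing insect communities on
host-plant leaflets, with the downstream stress-gradient stages: a tested,
reusable pipeline for asking whether gall morphospecies *segregate* across
leaflets (the statistical signature of interspecific competition) and
whether that segregation intensifies with environmental stress.

## The problem and the method

A site's community is a binary matrix: rows are gall morphospecies,
columns are individual galled leaflets (the sampling unit; every column
hosts at least one gall), and `x_ij = 1` means species *i* occurs on
leaflet *j*. For a species pair occupying `r_i` and `r_j` leaflets and
sharing `S` of them, the number of **checkerboard units** is

    CU = (r_i − S)(r_j − S)

and the **C-score** is the mean CU over all unordered species pairs —
larger values mean species overlap less than their abundances allow.

Whether an observed C-score is *large* is judged against a **fixed-fixed
null model**: the uniform distribution over all binary matrices with the
same row totals (species occurrence frequencies) and column totals
(species per leaflet). Null matrices are drawn by a sequential swap chain
that flips random 2×2 checkerboard submatrices (margin-preserving by
construction, aperiodic by lazy moves, thinned in attempted swaps so the
chain samples the fixed-margin family uniformly — verified in-package
against an exhaustive Gale–Ryser enumeration oracle). From the observed
statistic and the null ensemble the pipeline reports both one-tailed
permutation p-values with add-one correction,

    p_ge = (1 + #{null ≥ obs}) / (n + 1),    p_le = (1 + #{null ≤ obs}) / (n + 1),

(`p_ge` small ⇒ segregation, `p_le` small ⇒ aggregation) and two effect
sizes: `NES = (obs − mean_null) / mean_null` (used in the gradient
regressions) and the classical `SES = (obs − mean_null) / sd_null`.

The stress stages link per-site NES to three indicators: the **aridity
index** `AI = mean_m(P_m / PET_m)` over 24 monthly precipitation/
evapotranspiration pairs (lower = more arid), **specific leaf mass**
`sfm = disk dry mass / 0.38 cm²` (a sclerophylly proxy), and **PC1 of a
correlation-matrix PCA** over 11 soil-chemistry variables (pH, H+Al,
Al3+, Ca, Mg, P, K, SB, t, m, V), oriented so fertile sites score
positive. Gall diversity per plant is modelled with Poisson /
quasi-Poisson GLMs (site effects, deviance analysis) and a Poisson mixed
model with a random site intercept (sfm effect, likelihood-ratio test).

A synthetic-data generator plants known structure so every stage is
testable without field data: a pairwise-interaction leaflet model whose
parameter θ sets segregation strength (θ = 0 is an *exact* null for the
fixed-fixed test), plus seven-site gradients with monotone planted
environment–stress relations. See `docs/methods.md` for the model and its
caveats.

## Worked example

```python
from nullcooc import (CommunitySimConfig, RunConfig, analyze_site,
                      drop_empty_species, simulate_gall_community)

cfg = CommunitySimConfig(n_species=10, n_leaflets=137, theta=1.5, seed=42)
m = drop_empty_species(simulate_gall_community(cfg))
r = analyze_site(m, RunConfig(n_null=2_000, burn_in=10_000, thin=2_000, seed=1))
print(r.observed, r.null_summary.mean, r.p_ge, r.nes)
```

prints (see `examples/01_cscore_and_null_test.py`):

```
simulated 10 species x 137 leaflets, observed C-score = 218.49
null C-score over 2000 fixed-fixed matrices: min=212.16 mean=214.64 max=217.67
p(null >= obs) = 0.0005   p(null <= obs) = 1.0000
NES = +0.0179   SES = +4.59
```

The observed C-score exceeds every one of the 2,000 null values
(`p_ge = 1/2001`): the planted θ = 1.5 segregation is detected. On a full
simulated gradient (`examples/03_stress_gradient.py`) the three xeric
sites are flagged segregated (`p_ge` = .001–.003) while the four mesic
sites are not, and NES rises with sfm and falls with AI and soil PC1.

The other examples cover the enumeration oracle
(`02_enumeration_oracle.py`) and the diversity models
(`04_diversity_models.py`). A thin CLI mirrors the pipeline for shell
use: `nullcooc simulate`, `nullcooc run`, `nullcooc gradient`
(`--help` on each).

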