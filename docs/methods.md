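# Methods

## Demographic model family

The basic model has two contemporary populations P₁ (size N₁) and P₂ (size
q·N₁) that emerged τ·4N₁ generations ago from an ancestral population of
size (s₁+s₂)·N₁.  After the split P₁ changes exponentially from s₁·N₁ to
N₁ and P₂ from s₂·N₁ to q·N₁; a symmetric migration rate m (scaled by 4N₁)
connects them.  θ = 4N₁μ is the population mutation rate *per locus*.  The
named models fix or constrain subsets of {θ, q, τ, m, s₁, s₂}:

| model              | free                    | fixed / constrained      |
|--------------------|-------------------------|--------------------------|
| Constant           | θ, q, τ, m              | s₁=1, s₂=q               |
| Fraction-Growth    | θ, q, τ, m              | s₁=1, s₂=0.05            |
| NoMig              | θ, q, τ                 | m=0, s₁=1, s₂=0.3        |
| FixedS2            | θ, q, τ, m              | s₁=1, s₂=0.3             |
| SingleGrowMig      | θ, q, τ, m, s₂          | s₁=1                     |
| BothGrowNoMig      | θ, q, τ, s₁, s₂         | m=0                      |
| BothGrowMig        | θ, q, τ, m, s₁, s₂      | —                        |
| DecreasingMigration| θ, q, τ_m, τ₀, m, s₁, s₂| —                        |

"+Γ" variants add the Gamma shape α of the finite-sites mutation model as
a free parameter.  In DecreasingMigration the split time is τ₀+τ_m;
backwards in time migration is 0 on [0, τ₀), m/2 on [τ₀, τ₀+τ_m/2), and m
from there to the split.  The halving time is placed at the midpoint of
the migration span; the verbal description of this model is ambiguous on
that point, and the midpoint is the reading consistent with "migration
decreases to m/2 at 0.5·τ_m".

All free parameters are searched on the natural-log scale.  Default
natural ranges: θ ∈ [1.25, 125] per locus, q, s₁, s₂ ∈ [0.05, 20],
τ, m, τ_m ∈ [0.01, 5], τ₀ ∈ [0.005, 5], α ∈ [0.1, 10]; all overridable
per run.  These brackets comfortably contain published two-population
estimates for this model family; the log scale makes the uniform block
draws scale-free.

Unit conversion: with the per-site convention θ_site = c·N_e·μ and times
scaled in c·N_e generations (c = 4 for the ms convention, 2 for the
2N_e convention), N_e = θ_site/(c·μ) and the split time in years is
τ·c·N_e·g with generation time g.

## Simulation engine

Genealogies come from msprime behind an ms-compatible contract: haploid
(ploidy-1) populations of initial size x/2 for relative size x give the
pairwise coalescence rate 2/x per 4N₁ generations, exactly Hudson's
scaling; θ and the recombination rate ρ are per locus; migration rates are
4N₁-scaled.  Exponential size-change rates are derived from the endpoint
ratios and τ.  τ = 0 is clamped to 10⁻⁸ (effective panmixia).  The
outgroup is a single lineage whose population diverges at T·τ.

Infinite-sites data are produced two ways that share one distribution:

* explicit mutation dropping (binary alleles on a continuous genome) when
  haplotypes are needed — ms-dialect output, fixtures;
* for the estimation search, JSFS cell counts are drawn as Poisson
  variables with mean θ/L times the branch-mode joint allele-frequency
  spectrum of each locus.  Conditional on the genealogy this is exactly
  the infinite-sites sampling distribution of the per-class SNP counts,
  and it avoids per-site work.  Outgroup polarization falls out of the
  three-way spectrum: branches subtending the outgroup sample produce
  sites whose orientation flips, so their counts are added to the
  reflected cells (y₁−a, y₂−b).

The test suite checks the two routes against each other and against
closed-form coalescent expectations (Watterson's E[S], E[T_MRCA]).

## Finite-sites sequence evolution

The HKY generator is normalized to one expected substitution per unit
branch length and satisfies detailed balance; ti/tv is the *expected*
transition/transversion ratio at stationarity, related to κ by
ti/tv = κ(π_Aπ_G + π_Cπ_T)/((π_A+π_G)(π_C+π_T)) (0.5 at the Jukes–Cantor
point).  Site-rate heterogeneity is continuous Gamma(α, 1/α) (mean 1,
variance 1/α); discretized categories are deliberately not used.  Branch
lengths are scaled so that a site with rate multiplier γ accumulates
(θ/L)·γ expected substitutions per unit time, preserving E[pairwise
diversity] ≈ θ/L at small θ.

Evolution along the genealogy runs through msprime's mutation engine via
uniformization: with q_max the largest leave-rate of the normalized
generator Q, mutation events are placed at rate (θ/L)·γ_j·q_max under a
per-site rate map and resolved with the jump matrix P = Q/q_max (diagonal
filled with silent self-transitions).  This reproduces the HKY
continuous-time Markov chain exactly — including back and parallel
mutations — and is validated in the tests against the closed-form
Jukes–Cantor branch mismatch probability ¾(1−e^{−4t/3}) and against
stationarity.  Ancestral states are drawn from π.  Polarization treats
*any* base different from the outgroup base as derived, so multiple-hit
sites enter the JSFS exactly as the polarization rule dictates; columns
with gaps or ambiguity codes are dropped and counted.

Default finite-sites configuration: equal base frequencies, ti/tv = 2,
α = 0.7, outgroup divergence factor T = 2 (a typical wild-tomato-like
setting); all fields overridable.

## Summary statistics

The default 23-class partition crosses five mirrored frequency bands per
axis — {0}, low (1..⌈0.1y⌉), intermediate, high (the top band mirroring
the low one), {y} — into 25 cells and excludes the two singleton corner
cells (0,0) and (y₁,y₂).  Mirrored high/low bands matter because
mutations on the outgroup branch swap those classes.  The construction
needs y ≥ 4 per population; custom partitions can be supplied.  Class
sums conserve the total polarized SNP count by construction.

## Surrogate likelihood and search

Each statistic gets a Poisson GLM with log link, main effects only in the
log-parameters — interactions are deliberately omitted so per-block fits
remain identifiable with few simulations.  All 23 responses share one
design matrix, so the fits run through a single batched IRLS solver
(numerically identical to per-response weighted Poisson ML, cross-checked
against statsmodels in the tests).  Non-converging responses (separation,
runaway coefficients) fall back to a capped intercept-only model;
intercepts are capped at ±50 on the natural-log scale.  The surrogate
objective Σ(−e^{linear} + S·linear) is concave in the log-parameters, so
the within-block maximizer (L-BFGS-B with analytic gradient, multi-start
from the block corners on failure) is essentially unique.

Search defaults: k = 3 intervals per parameter in the initial grid,
s_ini = s_main = 40 simulations, s_final = 100, n_RP = 10 starting
points, refinement half-width r = ln 2, stopping tolerance ε = 0.1 with
patience t_stop = 3 and cap t_max = 100, best-list size n_B = 5, aging
weight w = 0.9.  The stopping rule ends a search once each of the last
t_stop score *changes* is at most ε.  Ties are broken by block/start
index; one master seed spawns independent substreams for the initial
search, refinement, and final evaluation, making runs bit-reproducible.

Two scaling devices keep large runs cheap without changing expectations,
both exact for the expected counts and exposed as options:

* **locus exposure** — expected class counts are proportional to the
  number of (exchangeable) loci, so fitting simulations may use fewer
  loci; the GLM intercepts shift by log(n_loc/n_loc_sim);
* **length exposure** (finite sites, ρ = 0 fitting simulations) — at
  fixed per-site θ the expected counts are proportional to the locus
  length, so fitting simulations may use shorter loci with the analogous
  offset.

Fitting simulations default to ρ = 0 even when the data have
recombination: expectations of the JSFS do not depend on ρ, only
per-dataset variances do.  The final s_final-simulation evaluation should
use unscaled simulations when the search ran on scaled ones (the
`simulate_final` argument); tiny scaled simulations can spuriously report
a zero mean for a rare class and veto a good candidate with a −∞ score.
The start point of each refined search is always included among the
final-evaluation candidates — when warm-starting it is the best known
point, and otherwise it costs one extra evaluation.

A practical caution from the package's own experiments: with very large
datasets (hundreds of loci, tens of thousands of SNPs) the composite
likelihood becomes so sharp that the *curvature error* of the log-linear
surrogate over a ±ln 2 block dominates the estimate.  The refinement
half-width should then be reduced (r ≈ 0.3 works well in the tests — the
maximizer bias shrinks quadratically in r) and the step count raised.

The ext_θ option fixes θ = 5 during all simulations (reducing the search
dimension by one) and estimates θ afterwards from the linearity of the
expected total SNP count in θ under infinite sites:
θ̂ = 5·(observed total)/(expected total at the fitted point).  This is an
infinite-sites heuristic; using it with finite-sites simulation triggers
a warning.

## Likelihood-ratio test and bootstrap

ℓLR is the plain difference of composite log-likelihoods (no factor 2);
because statistic dependencies are ignored, no χ² calibration is valid
and the null distribution is simulated: datasets generated at the fitted
null point, both models refitted per dataset, p = #{ℓLR* ≥ observed}/n
(a (k+1)/(n+1) variant is available).  Replicate refits warm-start at the
fitted null point (the generating point), with the full model's extra
parameters started at their lower bounds, and both refits share
per-replicate random numbers — variance reduction on the difference that
does not change the null distribution's location.  A model score of −∞
(an observed class the model cannot produce, e.g. multiple-hit-driven
classes under infinite sites) propagates as p = 1 for an observed −∞ and
as +∞ ratios with a warning otherwise.

Two further devices stabilize the simulated ratios at small fit budgets.
First, nested-candidate sharing: each replicate's full-model winner is
projected onto the null's free parameters and the null winner is embedded
into the full space (extra parameters at their lower bounds), and each
model takes the better of its two candidates — gains in the shared
parameters then cancel from the ratio, leaving only the full model's
extra-parameter gain, which is the quantity of interest.  Second, the
reported ratio comes from a dedicated evaluation stage with unscaled
simulations (``s_eval``): exposure-scaled means are noisier per
simulation, and a composite score at these SNP counts is sensitive to a
few percent of error in the per-class means.

Confidence intervals are bias-corrected (BC, not BCa) percentile
intervals from a parametric bootstrap: z₀ = Φ⁻¹(fraction of bootstrap
estimates below the point estimate), endpoints at percentiles
Φ(2z₀ ± z_{(1±level)/2}).  Bootstrap data may use a lower ρ than the
fitting simulations; lower ρ means more linkage and larger summary
variance, hence conservative (wider) intervals.  Nuisance parameters
(e.g. α) can be fixed during the refits.

## Synthetic data: what it does and does not emulate

The generator produces exactly the model's world: exchangeable,
free-recombining loci; panmictic demes with exponential size
trajectories; HKY+Γ (or infinite-sites) mutation; a single, correctly
aligned outgroup sequence; no sequencing error, missing data, selection,
gene conversion, or locus-to-locus mutation-rate variation.  Passing
tests therefore certify the estimator's behaviour *under the model*, not
robustness to the many ways real alignments violate it — except for the
one violation studied deliberately: estimating finite-sites data under
infinite-sites assumptions.

## Problem sizes used by the test suite

The simulation experiments in `tests/test_acceptance.py` are sized for a
single CPU:

* **Parameter recovery** — Constant model at (θ=10, q=2, τ=0.5, m=0.5),
  20 datasets of 200 loci × 1 kb, 25+25 samples, data ρ = 25; search with
  k = 2, s_ini = 6, s_main = 8 (+ corners), n_RP = 2, r = 0.3, t_max = 11,
  s_final = 10, fitting simulations at 50 loci via the exposure offset.
  θ, q, τ each within ±0.30 log error in ≥ 80% of runs.
* **Gene-flow LRT** — 100 null datasets of 7 loci × 1250 bp at the
  no-migration HKY+Γ point (θ_site = 0.012, q = 10, τ = 0.21, α = 0.69),
  ti/tv = 2, T = 2, data ρ = 25, with 22+21 sampled sequences;
  warm-started refits with 300 bp fitting simulations, nested-candidate
  sharing, and a 24-simulation unscaled decision stage per model.  The
  fraction of null ratios reaching the observed 13.95 stays within 0.01.
* **Infinite-sites bias** — Fraction-Growth at θ_site = 0.05 (θ = 62.5
  per 1250 bp locus), α = 0.2, ti/tv = 2, T = 3, m = 0.1, 20 datasets of
  15 loci with 44+43 samples.  Medians over replicates: infinite-sites
  fits underestimate θ and overestimate τ and m; finite-sites refits
  (α free) shrink all three median biases.  The bias directions are a
  property of this high-θ, strongly heterogeneous regime with realistic
  sample sizes; at very small samples or short loci the misspecified
  optimum can move elsewhere.
* Watterson check at 10⁴ single-site loci; GLM recovery at 500 design
  points; optimizer-vs-grid on 20 instances; BC-bootstrap coverage on a
  Poisson-mean toy problem over 200 meta-replicates.

## Known limitations

* Two contemporary populations only; symmetric migration; no selection.
* The composite likelihood ignores linkage, so reported scores are not
  comparable across datasets with different ρ, and interval/test
  calibration relies on simulation rather than asymptotics.
* The 23-class partition is one reasonable mirrored-band construction;
  the class boundaries are configurable.
* GLM surrogates are local log-linear approximations; see the caution on
  the refinement half-width above.
* The ext_θ heuristic is undefined under finite sites.
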