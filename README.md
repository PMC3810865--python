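# pyjaatha

Composite-likelihood estimation of demographic parameters for two recently
diverged populations or species, from the joint site frequency spectrum
(JSFS) of multi-locus SNP data polarized against an outgroup.

## Who this is for

Population geneticists fitting isolation-with-migration speciation models —
a population of size *N₁* and one of size *q·N₁* that split τ·4*N₁*
generations ago from an ancestral population, with symmetric scaled
migration *m* and exponential post-split size changes — to alignments of
many loci sampled from two populations plus an outgroup.  Because the
method needs only summary statistics and relatively few simulations, it
scales from a handful of Sanger loci to genome-wide NGS SNP sets, and it
can simulate sequences under a finite-sites HKY + Γ mutation model, which
matters whenever multiple hits are common (roughly θ per site above 0.01):
assuming infinite sites on such data underestimates θ and overestimates
divergence times and migration rates, sometimes by orders of magnitude.

## The method

The data **D** (y₁ and y₂ sampled sequences per population) are summarized
by binning the JSFS *J[a,b]* — the number of SNPs whose derived allele
(i.e. the allele differing from the outgroup base) is carried by *a*
sequences of P₁ and *b* of P₂ — into n_SS = 23 classes {Aᵢ} partitioning
{0..y₁}×{0..y₂} minus the invisible (0,0) and fixed (y₁,y₂) cells.
Treating the class sums S₁..S₂₃ as independent Poisson variables (unlinked
SNPs), the composite log-likelihood of a parameter vector Φ is

    ℓ(Φ) = Σᵢ [ −λᵢ(Φ) + Sᵢ·ln λᵢ(Φ) − ln Sᵢ! ]

where λᵢ(Φ) = E[Sᵢ] is approximated locally by a Poisson GLM with log
link, log-linear in the log-parameters, fitted to coalescent simulations
(msprime supplies the genealogies; sequences evolve under HKY + Γ when a
finite-sites configuration is given).  The search has two phases: a coarse
block search over the kⁿ-tiled log-parameter space, then, from each of the
n_RP best starting points, iterated refinement steps — simulate inside a
hypercube around the current estimate (corner points included), refit the
GLMs on the pooled simulation records (old records are reused only while
the estimate stays inside their block, down-weighted by wᵃᵍᵉ), and
re-maximize by box-constrained quasi-Newton search.  Each final candidate
is re-scored with s_final independent simulations.  On top of the
estimator sit a simulation-calibrated composite log-likelihood-ratio test
for gene flow (no χ² approximation is valid for composite likelihoods) and
bias-corrected parametric-bootstrap confidence intervals.

## Worked example

Simulate a 200-locus dataset under the "Constant" model (no post-split
size change in either population) and re-estimate its four parameters:

```python
import numpy as np
from pyjaatha import (DatasetSimulator, LocusConfig, SearchSettings,
                      build_named_model, default_partition, run_estimation,
                      summarize_jsfs)

model = build_named_model("Constant")            # free: theta, q, tau, m
truth = {"theta": 10.0, "q": 2.0, "tau": 0.5, "m": 0.5}

data_cfg = LocusConfig(n_loc=200, y1=25, y2=25, seq_length_bp=1000,
                       rho=25.0, outgroup_factor=2.0)
fit_cfg = LocusConfig(n_loc=200, y1=25, y2=25, seq_length_bp=1000,
                      rho=0.0, outgroup_factor=2.0)
part = default_partition(25, 25)

data_sim = DatasetSimulator(model, data_cfg, part)
observed = summarize_jsfs(
    data_sim.simulate_jsfs(model.natural_point(truth),
                           np.random.default_rng(1000)), part)

fit_sim = DatasetSimulator(model, fit_cfg, part, n_loc_sim=50)
settings = SearchSettings(k=2, s_ini=6, s_main=8, s_final=10, n_rp=2,
                          n_b=2, t_max=11, t_stop=4, epsilon=3.0, w=0.7,
                          r=0.3)
result = run_estimation(model, fit_sim, settings, observed, seed=500)
print(result.summary())
```

This prints (seed-reproducible):

```
Constant: theta=10.22, q=1.969, tau=0.5043, m=0.4822  log-composite-likelihood=-242.74
```

i.e. all four parameters are recovered close to the generating values —
θ̂ = 10.2 (truth 10), q̂ = 1.97 (truth 2), τ̂ = 0.50 (truth 0.5),
m̂ = 0.48 (truth 0.5) — and the reported score is the Poisson composite
log-likelihood of the 23 observed class counts at the estimate (here
estimated from 10 exposure-scaled simulations, so its absolute value is
noisier than the parameter estimates themselves).  A
command-line interface (`pyjaatha simulate | jsfs | estimate | lrt |
bootstrap`) wraps the same pipelines around a JSON/YAML run configuration.

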