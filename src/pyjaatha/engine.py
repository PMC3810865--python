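"""Coalescent simulation of two-population genealogies and infinite-sites data.

The contract is ms-compatible: times are measured in units of 4*N1
generations, ``theta`` and ``rho`` are per-locus rates scaled by 4*N1, and
migration rates follow the ``4*N1*m`` convention.  msprime provides the
backward-time simulator; the ms time scale is obtained by using haploid
(ploidy-1) populations whose ``initial_size`` equals half the relative size,
so a population of relative size ``x`` has pairwise coalescence rate ``2/x``
per unit time, exactly as in ms.

Two routes produce infinite-sites SNP data:

* :func:`add_ism_mutations` drops actual mutations on the genealogy
  (infinite-sites, binary alleles) and is used when haplotypes are needed
  (ms-dialect output, fixtures).
* :func:`simulate_ism_jsfs` samples the joint SFS directly as independent
  Poisson counts with mean ``theta/L`` times the branch-mode joint allele
  frequency spectrum.  Conditional on the genealogy this is the exact
  distribution of infinite-sites SNP counts per frequency class, and it is
  considerably faster; it is the route used inside the estimation search.

Polarization follows the outgroup rule: when an outgroup lineage (divergence
``T * tau`` before present) is included, an allele is "derived" when it
differs from the outgroup allele, so mutations on the outgroup stem flip the
orientation of a site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import msprime
import numpy as np
import tskit

from .models import DemographyParams, migration_epochs

__all__ = [
    "LocusConfig",
    "build_demography",
    "simulate_genealogies",
    "add_ism_mutations",
    "ism_jsfs_from_ts",
    "simulate_ism_jsfs",
    "simulate_ism_dataset",
]

_MIN_TIME = 1e-8  # degenerate tau=0 is clamped to this (effective panmixia)


@dataclass(frozen=True)
class LocusConfig:
    """Per-locus sampling configuration.

    ``rho`` is the per-locus population recombination rate (4*N1 scaled);
    ``outgroup_factor`` is the outgroup divergence T (outgroup splits at
    ``T * tau`` before present); ``None`` disables the outgroup lineage and
    polarization then uses the true ancestral state.
    """

    n_loc: int
    y1: int
    y2: int
    seq_length_bp: int = 1000
    rho: float = 0.0
    outgroup_factor: float | None = None

    def __post_init__(self):
        if self.y1 < 2 or self.y2 < 2:
            raise ValueError("need at least 2 sampled sequences per population")
        if self.n_loc < 1:
            raise ValueError("n_loc must be >= 1")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.outgroup_factor is not None and self.outgroup_factor < 1:
            raise ValueError("outgroup divergence factor T must be >= 1")

    @property
    def has_outgroup(self) -> bool:
        return self.outgroup_factor is not None


def build_demography(params: DemographyParams,
                     outgroup_factor: float | None = None) -> msprime.Demography:
    """Translate a parameter combination into an msprime demography on the
    ms time scale (see module docstring for the size convention)."""
    tau = max(params.tau, _MIN_TIME)
    d = msprime.Demography()
    g1 = np.log(1.0 / params.s1) / tau
    g2 = np.log(params.q / params.s2) / tau
    d.add_population(name="P1", initial_size=0.5, growth_rate=g1)
    d.add_population(name="P2", initial_size=params.q / 2.0, growth_rate=g2)
    d.add_population(name="ANC", initial_size=(params.s1 + params.s2) / 2.0)

    if params.tau_0 is not None and params.tau_m is not None and params.tau > 0:
        epochs, _split = migration_epochs(params)
        first_rate = next((r for a, b, r in epochs if a <= _MIN_TIME < b), 0.0)
        d.set_symmetric_migration_rate(["P1", "P2"], first_rate)
        for start, _end, rate in epochs:
            if start <= _MIN_TIME:
                continue
            d.add_symmetric_migration_rate_change(
                time=start, populations=["P1", "P2"], rate=rate)
    else:
        d.set_symmetric_migration_rate(["P1", "P2"], params.m)

    d.add_population_split(time=tau, derived=["P1", "P2"], ancestral="ANC")
    if outgroup_factor is not None:
        t_out = max(outgroup_factor * tau, 2 * _MIN_TIME)
        d.add_population(name="OUT", initial_size=0.5)
        d.add_population(name="ROOT", initial_size=(params.s1 + params.s2) / 2.0)
        d.add_population_split(time=t_out, derived=["ANC", "OUT"], ancestral="ROOT")
    d.sort_events()
    return d


def _msprime_seeds(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(1, 2**31 - 1, size=n)


def simulate_genealogies(params: DemographyParams, locus_config: LocusConfig,
                         seed: int | np.random.Generator) -> Iterator[tskit.TreeSequence]:
    """Simulate ``n_loc`` independent per-locus genealogies (ancestry only).

    Deterministic given the seed.  Each returned tree sequence carries the
    sample ordering P1 (y1), P2 (y2), then the outgroup (if configured).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    demography = build_demography(params, locus_config.outgroup_factor)
    samples = {"P1": locus_config.y1, "P2": locus_config.y2}
    if locus_config.has_outgroup:
        samples["OUT"] = 1
    try:
        yield from msprime.sim_ancestry(
            samples=samples, demography=demography, ploidy=1,
            sequence_length=locus_config.seq_length_bp,
            recombination_rate=locus_config.rho / locus_config.seq_length_bp,
            random_seed=int(_msprime_seeds(rng, 1)[0]),
            num_replicates=locus_config.n_loc)
    except Exception as err:  # surface the offending event schedule
        raise RuntimeError(
            f"coalescent simulation failed for {params!r}: {err}") from err


def add_ism_mutations(ts: tskit.TreeSequence, theta: float,
                      seed: int | np.random.Generator) -> tskit.TreeSequence:
    """Drop infinite-sites mutations at total per-locus rate ``theta`` per
    unit (4*N1) time.  Every mutation hits a new (continuous) position;
    alleles are 0 (ancestral) / 1 (derived)."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return msprime.sim_mutations(
        ts, rate=theta / ts.sequence_length, model=msprime.BinaryMutationModel(),
        discrete_genome=False, random_seed=int(_msprime_seeds(rng, 1)[0]))


def _sample_sets(ts: tskit.TreeSequence, locus_config: LocusConfig):
    p1 = ts.samples(population=0)
    p2 = ts.samples(population=1)
    out = ts.samples(population=3) if locus_config.has_outgroup else None
    return p1, p2, out


def ism_jsfs_from_ts(mts: tskit.TreeSequence, locus_config: LocusConfig) -> np.ndarray:
    """Joint SFS of a mutated (binary-allele) tree sequence, polarized
    against the outgroup sample when present."""
    y1, y2 = locus_config.y1, locus_config.y2
    J = np.zeros((y1 + 1, y2 + 1), dtype=np.int64)
    if mts.num_sites == 0:
        return J
    G = mts.genotype_matrix()
    p1, p2, out = _sample_sets(mts, locus_config)
    if out is not None:
        ref = G[:, out[0]][:, None]
    else:
        ref = np.zeros((G.shape[0], 1), dtype=G.dtype)
    a = (G[:, p1] != ref).sum(axis=1)
    b = (G[:, p2] != ref).sum(axis=1)
    keep = (a > 0) | (b > 0)
    np.add.at(J, (a[keep], b[keep]), 1)
    return J


def simulate_ism_jsfs(params: DemographyParams, locus_config: LocusConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Simulate the pooled joint SFS of ``n_loc`` infinite-sites loci.

    SNP counts per JSFS cell are Poisson draws with mean ``theta/L`` times
    the branch-mode joint AFS of each locus — the exact conditional
    distribution under the infinite-sites model.  Outgroup polarization is
    obtained from the three-way branch AFS: branches subtending the outgroup
    sample produce sites whose orientation is flipped.
    """
    y1, y2 = locus_config.y1, locus_config.y2
    L = locus_config.seq_length_bp
    J = np.zeros((y1 + 1, y2 + 1), dtype=np.int64)
    for ts in simulate_genealogies(params, locus_config, rng):
        p1, p2, out = _sample_sets(ts, locus_config)
        if out is not None:
            afs = ts.allele_frequency_spectrum(
                [p1, p2, out], mode="branch", polarised=True, span_normalise=False)
            lam = (params.theta / L) * afs
            counts = rng.poisson(lam)
            J += counts[:, :, 0]
            J += counts[::-1, ::-1, 1]  # derived in outgroup: orientation flips
        else:
            afs = ts.allele_frequency_spectrum(
                [p1, p2], mode="branch", polarised=True, span_normalise=False)
            J += rng.poisson((params.theta / L) * afs)
    J[0, 0] = 0
    return J


def simulate_ism_dataset(params: DemographyParams, locus_config: LocusConfig,
                         seed: int | np.random.Generator) -> np.ndarray:
    """Pooled joint SFS for a full infinite-sites dataset (deterministic
    given seed).  Thin wrapper around :func:`simulate_ism_jsfs`."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return simulate_ism_jsfs(params, locus_config, rng)
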