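"""Finite-sites sequence evolution (HKY + Gamma) along simulated genealogies.

Sequences evolve under the HKY substitution model with continuous
Gamma-distributed site-rate multipliers (shape ``alpha``, scale ``1/alpha``,
mean 1).  The rate matrix is normalized to one expected substitution per unit
branch length, and the per-locus population mutation rate ``theta`` is
converted to a per-site rate ``theta / L`` per unit (4*N1) time, so that
pairwise diversity per site approaches ``theta / L`` for small ``theta``.

Evolution along the genealogy is delegated to msprime's mutation engine via
uniformization: with ``q_max`` the largest leave-rate of the normalized HKY
generator Q, mutation *events* are placed at rate ``theta_site * rate_j *
q_max`` and resolved with the jump matrix ``P = Q / q_max`` (diagonal filled
so rows sum to 1, i.e. silent self-transitions).  This reproduces the HKY
continuous-time Markov chain exactly, including back and parallel mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import tskit

__all__ = [
    "NUCLEOTIDES",
    "FiniteSitesConfig",
    "Alignment",
    "titv_to_kappa",
    "expected_titv",
    "hky_rate_matrix",
    "hky_mutation_model",
    "draw_site_rates",
    "evolve_site_counts",
    "evolve_alignment",
]

NUCLEOTIDES = ("A", "C", "G", "T")
# purines A, G at indices 0, 2; pyrimidines C, T at 1, 3
_TRANSITION_PAIRS = ((0, 2), (2, 0), (1, 3), (3, 1))


@dataclass(frozen=True)
class FiniteSitesConfig:
    """HKY+Gamma configuration.

    Defaults follow the tomato ("Solanum") setup: ti/tv = 2, alpha = 0.7,
    outgroup divergence factor T = 2, with equal base frequencies (observed
    frequencies can be supplied instead).
    """

    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    titv: float = 2.0
    alpha: float = 0.7
    outgroup_factor: float = 2.0

    def __post_init__(self):
        f = np.asarray(self.base_freqs, dtype=float)
        if f.shape != (4,) or np.any(f <= 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError("base_freqs must be 4 positive values summing to 1")
        object.__setattr__(self, "base_freqs", tuple(float(x) for x in f))
        if self.titv <= 0 or self.alpha <= 0:
            raise ValueError("titv and alpha must be > 0")
        if self.outgroup_factor < 1:
            raise ValueError("outgroup divergence factor T must be >= 1")

    @property
    def kappa(self) -> float:
        return titv_to_kappa(self.titv, self.base_freqs)


@dataclass
class Alignment:
    """Nucleotide matrix: rows ordered P1 samples, P2 samples, then one
    outgroup row (when present); columns are sites."""

    seqs: np.ndarray  # (n_rows, L) array of single characters
    y1: int
    y2: int
    has_outgroup: bool = True
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        expected = self.y1 + self.y2 + (1 if self.has_outgroup else 0)
        if self.seqs.shape[0] != expected:
            raise ValueError(
                f"alignment has {self.seqs.shape[0]} rows, expected {expected}")
        if not self.ids:
            self.ids = ([f"P1_{i}" for i in range(self.y1)]
                        + [f"P2_{i}" for i in range(self.y2)]
                        + (["outgroup"] if self.has_outgroup else []))

    @property
    def n_sites(self) -> int:
        return self.seqs.shape[1]

    @property
    def p1_rows(self) -> slice:
        return slice(0, self.y1)

    @property
    def p2_rows(self) -> slice:
        return slice(self.y1, self.y1 + self.y2)

    @property
    def outgroup_row(self) -> np.ndarray:
        if not self.has_outgroup:
            raise ValueError("alignment has no outgroup row")
        return self.seqs[-1]


def titv_to_kappa(titv: float, base_freqs) -> float:
    """Invert the expected transition/transversion ratio into the HKY rate
    ratio kappa.

    The expected ratio at stationarity is
    ``titv = kappa * (pA*pG + pC*pT) / ((pA+pG) * (pC+pT))`` and equals 0.5
    at the Jukes-Cantor point (kappa = 1, equal frequencies).
    """
    if titv <= 0:
        raise ValueError("titv must be > 0")
    pA, pC, pG, pT = np.asarray(base_freqs, dtype=float)
    purines, pyrimidines = pA + pG, pC + pT
    ts_mass = pA * pG + pC * pT
    if ts_mass <= 0 or purines <= 0 or pyrimidines <= 0:
        raise ValueError("degenerate base frequencies: a purine/pyrimidine class is empty")
    return titv * purines * pyrimidines / ts_mass


def expected_titv(kappa: float, base_freqs) -> float:
    """Expected transition/transversion ratio implied by HKY at stationarity
    (inverse of :func:`titv_to_kappa`)."""
    pA, pC, pG, pT = np.asarray(base_freqs, dtype=float)
    return kappa * (pA * pG + pC * pT) / ((pA + pG) * (pC + pT))


def hky_rate_matrix(base_freqs, kappa: float) -> np.ndarray:
    """HKY generator with rows summing to zero, satisfying detailed balance
    and normalized to one expected substitution per unit branch length."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    pi = np.asarray(base_freqs, dtype=float)
    if pi.shape != (4,) or np.any(pi <= 0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("base_freqs must be 4 positive values summing to 1")
    Q = np.tile(pi, (4, 1))
    for i, j in _TRANSITION_PAIRS:
        Q[i, j] *= kappa
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    return Q / rate


def hky_mutation_model(base_freqs, kappa: float):
    """Uniformized msprime mutation model for the normalized HKY chain.

    Returns ``(model, event_rate_scale)``: placing mutation events at rate
    ``event_rate_scale`` times the desired substitution-time scaling and
    resolving them with ``model`` reproduces the HKY process exactly.
    """
    Q = hky_rate_matrix(base_freqs, kappa)
    leave = -np.diag(Q)
    q_max = float(leave.max())
    P = Q / q_max
    np.fill_diagonal(P, 1.0 - leave / q_max)
    model = msprime.MatrixMutationModel(
        list(NUCLEOTIDES),
        root_distribution=np.asarray(base_freqs, dtype=float),
        transition_matrix=P)
    return model, q_max


def draw_site_rates(alpha: float, n_sites: int,
                    seed: int | np.random.Generator) -> np.ndarray:
    """I.i.d. per-site rate multipliers from Gamma(shape alpha, scale
    1/alpha); mean 1, variance 1/alpha."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.gamma(alpha, 1.0 / alpha, size=n_sites)


def evolve_site_counts(ts: tskit.TreeSequence, config: FiniteSitesConfig,
                       theta: float, seed: int | np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site derived counts ``(a, b)`` under HKY+Gamma, against the
    simulated outgroup base.

    Equivalent to :func:`evolve_alignment` followed by polarization, but
    skips materializing the alignment (monomorphic columns carry no
    information); used by the estimation search where only the joint SFS is
    needed.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p1 = ts.samples(population=0)
    p2 = ts.samples(population=1)
    out = ts.samples(population=3)
    if len(out) == 0:
        raise ValueError("genealogy lacks the outgroup lineage required for polarization")
    L = int(ts.sequence_length)
    if theta == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    model, q_max = hky_mutation_model(config.base_freqs, config.kappa)
    rates = draw_site_rates(config.alpha, L, rng)
    rate_map = msprime.RateMap(position=np.arange(L + 1, dtype=float),
                               rate=(theta / L) * q_max * rates)
    mts = msprime.sim_mutations(
        ts, rate=rate_map, model=model, discrete_genome=True,
        random_seed=int(rng.integers(1, 2**31 - 1)))
    if mts.num_sites == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    G = mts.genotype_matrix(alleles=NUCLEOTIDES)
    ref = G[:, out[0]][:, None]
    a = (G[:, p1] != ref).sum(axis=1)
    b = (G[:, p2] != ref).sum(axis=1)
    keep = (a > 0) | (b > 0)
    return a[keep], b[keep]


def evolve_alignment(ts: tskit.TreeSequence, config: FiniteSitesConfig,
                     theta: float, seed: int | np.random.Generator,
                     y1: int | None = None, y2: int | None = None) -> Alignment:
    """Evolve nucleotide sequences along a simulated genealogy.

    ``ts`` must include the outgroup lineage (sample sets are read from the
    tree sequence populations).  ``theta`` is the per-locus population
    mutation rate; sites evolve at ``theta/L`` per unit time scaled by their
    Gamma rate multiplier.  Deterministic given the seed.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p1 = ts.samples(population=0)
    p2 = ts.samples(population=1)
    try:
        out = ts.samples(population=3)
    except (ValueError, IndexError):
        out = np.array([], dtype=np.int32)
    if len(out) == 0:
        raise ValueError("genealogy lacks the outgroup lineage required for polarization")
    if y1 is None:
        y1 = len(p1)
    if y2 is None:
        y2 = len(p2)

    L = int(ts.sequence_length)
    pi = np.asarray(config.base_freqs, dtype=float)
    order = np.concatenate([p1, p2, out[:1]])

    # stationary draw for every column; mutated columns are overwritten below
    codes = rng.choice(4, size=L, p=pi)
    aln = np.tile(np.array(NUCLEOTIDES)[codes], (len(order), 1))

    if theta > 0:
        model, q_max = hky_mutation_model(config.base_freqs, config.kappa)
        rates = draw_site_rates(config.alpha, L, rng)
        rate_map = msprime.RateMap(position=np.arange(L + 1, dtype=float),
                                   rate=(theta / L) * q_max * rates)
        mts = msprime.sim_mutations(
            ts, rate=rate_map, model=model, discrete_genome=True,
            random_seed=int(rng.integers(1, 2**31 - 1)))
        if mts.num_sites:
            G = mts.genotype_matrix(alleles=NUCLEOTIDES)
            positions = mts.tables.sites.position.astype(int)
            aln[:, positions] = np.array(NUCLEOTIDES)[G[:, order]].T
    return Alignment(seqs=aln, y1=y1, y2=y2, has_outgroup=True)
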