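"""The two-phase composite-likelihood search.

Phase 1 (initial search) tiles the log-parameter space into ``k^n`` equal
blocks, simulates ``s_ini`` datasets per block at uniformly drawn
log-parameter points, fits the Poisson-GLM surrogate per block, and keeps
the ``n_RP`` block maximizers with the highest scores as starting points.

Phase 2 (refined search) iterates *steps* from each start: place a block of
half-width ``r`` around the current estimate, simulate ``s_main`` datasets at
uniform points (plus the 2^n block corners), refit the surrogate on the
pooled simulation records — reusing records of previous blocks only while
the current estimate stays inside their block, with weights ``w^age`` — and
re-maximize within the current block.  Iteration stops once the score has
changed by at most ``epsilon`` in each of the last ``t_stop`` steps, or at
``t_max`` steps.  A best-list of the ``n_B`` highest-scoring points is kept.

Finally every best-list candidate is re-scored with ``s_final`` independent
simulations (the GLM-free composite likelihood), and the highest-likelihood
point is reported.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .engine import LocusConfig, simulate_genealogies, simulate_ism_jsfs
from .finite_sites import FiniteSitesConfig, evolve_site_counts
from .models import ModelSpec
from .summaries import Partition, build_jsfs, default_partition, summarize_jsfs
from .surrogate import Block, GlmSurrogate, composite_loglik, final_composite_loglik, \
    fit_surrogate, maximize_in_block

__all__ = [
    "SearchSettings",
    "DatasetSimulator",
    "SimPool",
    "EstimationResult",
    "initial_search",
    "jaatha_step",
    "refined_search",
    "run_estimation",
    "estimate_theta_ext",
]

logger = logging.getLogger(__name__)

_BLOCK_CAP = 10**5


@dataclass
class SearchSettings:
    """Tunable settings of the two-phase search (see module docstring)."""

    k: int = 3                      # intervals per parameter in the initial grid
    s_ini: int = 40                 # simulations per initial block
    s_main: int = 40                # simulations per refined step
    s_final: int = 100              # simulations per final evaluation
    n_rp: int = 10                  # retained starting points
    r: float = float(np.log(2.0))   # refined-block half-width (log scale)
    epsilon: float = 0.1            # score-change stopping tolerance
    t_stop: int = 3                 # patience (steps within epsilon)
    t_max: int = 100                # hard cap on refined steps
    n_b: int = 5                    # best-list size
    w: float = 0.9                  # per-age simulation weight base
    include_corners: bool = True    # simulate the 2^n block corners each step
    ext_theta: bool = False         # fix theta=5 and estimate it separately

    def __post_init__(self):
        for name in ("k", "s_ini", "s_main", "s_final", "n_rp", "t_stop", "t_max", "n_b"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must be in [0, 1]")
        if self.epsilon <= 0 or self.r <= 0:
            raise ValueError("epsilon and r must be > 0")


class DatasetSimulator:
    """Maps a log-parameter point to a simulated summary-statistic vector.

    Infinite-sites mode when ``fsm_config`` is None; otherwise genealogies
    are evolved under HKY+Gamma (the Gamma shape comes from the model's free
    ``alpha`` when present, else from the configuration) and polarized
    against the simulated outgroup sequence.
    """

    def __init__(self, model: ModelSpec, locus_config: LocusConfig,
                 partition: Partition | None = None,
                 fsm_config: FiniteSitesConfig | None = None,
                 n_loc_sim: int | None = None,
                 seq_length_sim: int | None = None):
        self.model = model
        self.locus_config = locus_config
        self.partition = partition or default_partition(locus_config.y1, locus_config.y2)
        self.fsm_config = fsm_config
        if fsm_config is not None and not locus_config.has_outgroup:
            self.locus_config = LocusConfig(
                n_loc=locus_config.n_loc, y1=locus_config.y1, y2=locus_config.y2,
                seq_length_bp=locus_config.seq_length_bp, rho=locus_config.rho,
                outgroup_factor=fsm_config.outgroup_factor)
        # Loci are exchangeable and (without recombination) sites within a
        # locus are exchangeable given the genealogy, so expected summary
        # counts are proportional to n_loc and, at fixed per-site theta, to
        # the locus length.  Simulations may therefore use fewer/shorter
        # loci and enter the Poisson GLMs with a log(count_scale) exposure
        # offset (applied by the search).
        self.count_scale = 1.0
        self.theta_scale = 1.0
        n_loc = n_loc_sim or self.locus_config.n_loc
        length = seq_length_sim or self.locus_config.seq_length_bp
        if (n_loc, length) != (self.locus_config.n_loc, self.locus_config.seq_length_bp):
            if seq_length_sim is not None and fsm_config is None:
                raise ValueError("seq_length_sim applies to finite-sites "
                                 "simulation only (infinite-sites counts do "
                                 "not depend on the locus length)")
            self.count_scale = ((self.locus_config.n_loc / n_loc)
                                * (self.locus_config.seq_length_bp / length))
            self.theta_scale = length / self.locus_config.seq_length_bp
            self.locus_config = LocusConfig(
                n_loc=n_loc, y1=self.locus_config.y1, y2=self.locus_config.y2,
                seq_length_bp=length, rho=self.locus_config.rho,
                outgroup_factor=self.locus_config.outgroup_factor)

    @property
    def n_stats(self) -> int:
        return self.partition.n_classes

    def simulate_jsfs(self, point: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        params = self.model.to_demography_params(point)
        if self.fsm_config is None:
            return simulate_ism_jsfs(params, self.locus_config, rng)
        values = self.model.resolve(point)
        cfg = self.fsm_config
        if "alpha" in values:
            cfg = FiniteSitesConfig(base_freqs=cfg.base_freqs, titv=cfg.titv,
                                    alpha=values["alpha"],
                                    outgroup_factor=cfg.outgroup_factor)
        lc = self.locus_config
        theta = params.theta * self.theta_scale  # preserve per-site theta
        J = np.zeros((lc.y1 + 1, lc.y2 + 1), dtype=np.int64)
        for ts in simulate_genealogies(params, lc, rng):
            a, b = evolve_site_counts(ts, cfg, theta, rng)
            J += build_jsfs(a, b, lc.y1, lc.y2)
        return J

    def __call__(self, point: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return summarize_jsfs(self.simulate_jsfs(point, rng), self.partition)


@dataclass
class _PoolRecord:
    points: np.ndarray   # (s, n) log-parameter points
    counts: np.ndarray   # (s, n_stats)
    block: Block
    age: int = 0


@dataclass
class SimPool:
    """Simulation records with provenance (originating block) and age."""

    records: list[_PoolRecord] = field(default_factory=list)

    def add(self, points, counts, block):
        self.records.append(_PoolRecord(np.asarray(points), np.asarray(counts), block))

    def age_all(self):
        for rec in self.records:
            rec.age += 1

    def purge(self, estimate: np.ndarray):
        """Drop records whose block no longer contains the estimate."""
        self.records = [r for r in self.records if r.block.contains(estimate)]

    def design(self, w: float):
        points = np.concatenate([r.points for r in self.records])
        counts = np.concatenate([r.counts for r in self.records])
        weights = np.concatenate([
            np.full(len(r.points), w ** r.age) for r in self.records])
        return points, counts, weights

    @property
    def size(self) -> int:
        return sum(len(r.points) for r in self.records)


@dataclass
class _SearchState:
    estimate: np.ndarray
    pool: SimPool
    best: list[tuple[np.ndarray, float]] = field(default_factory=list)
    history: list[float] = field(default_factory=list)
    step: int = 0

    def update_best(self, point: np.ndarray, score: float, n_b: int):
        if any(np.array_equal(point, p) for p, _ in self.best):
            return
        self.best.append((point.copy(), score))
        self.best.sort(key=lambda ps: -ps[1])
        del self.best[n_b:]


@dataclass
class EstimationResult:
    """Outcome of a full estimation run."""

    model_name: str
    param_names: list[str]
    best_point: np.ndarray           # log scale
    best_params: dict[str, float]    # natural scale, free parameters
    best_loglik: float
    candidates: list[dict]           # per-start winners with scores
    converged: bool
    seed: int | None = None
    settings: dict | None = None

    def summary(self) -> str:
        pars = ", ".join(f"{k}={v:.4g}" for k, v in self.best_params.items())
        return (f"{self.model_name}: {pars}  "
                f"log-composite-likelihood={self.best_loglik:.2f}")


def _simulate_batch(simulate, points, rng):
    return np.array([simulate(p, rng) for p in points], dtype=float)


def _fit_with_exposure(simulate, points, counts, weights=None) -> GlmSurrogate:
    """Fit the surrogate, shifting intercepts by the simulator's exposure
    offset when simulations use fewer loci than the observed dataset."""
    surr = fit_surrogate(points, counts, weights=weights)
    scale = getattr(simulate, "count_scale", 1.0)
    if scale != 1.0:
        surr.coef[:, 0] += np.log(scale)
    return surr


def initial_search(model: ModelSpec, simulate, settings: SearchSettings,
                   observed_S: np.ndarray, rng: np.random.Generator
                   ) -> list[np.ndarray]:
    """Coarse block search returning up to ``n_RP`` starting points, ordered
    by decreasing surrogate score (ties broken by block index)."""
    n = model.n_params
    if settings.k ** n > _BLOCK_CAP:
        raise ValueError(
            f"initial grid of {settings.k}^{n} blocks exceeds the cap of "
            f"{_BLOCK_CAP}; consider ext_theta or fewer free parameters")
    bounds = model.log_bounds
    edges = [np.linspace(lo, hi, settings.k + 1) for lo, hi in bounds]
    scored: list[tuple[float, int, np.ndarray]] = []
    for b_idx, cell in enumerate(itertools.product(*(range(settings.k),) * n)):
        block = Block(bounds=np.array(
            [(edges[d][c], edges[d][c + 1]) for d, c in enumerate(cell)]))
        points = model.sample_uniform(rng, settings.s_ini, bounds=block.bounds)
        counts = _simulate_batch(simulate, points, rng)
        surr = _fit_with_exposure(simulate, points, counts)
        point, score = maximize_in_block(surr, observed_S, block)
        scored.append((score, b_idx, point))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [point for _, _, point in scored[: settings.n_rp]]


def jaatha_step(state: _SearchState, model: ModelSpec, simulate,
                settings: SearchSettings, observed_S: np.ndarray,
                rng: np.random.Generator) -> _SearchState:
    """One refined-search iteration (see module docstring)."""
    block = Block.around(state.estimate, settings.r, model.log_bounds)
    points = model.sample_uniform(rng, settings.s_main, bounds=block.bounds)
    if settings.include_corners:
        points = np.vstack([points, block.corners()])
    counts = _simulate_batch(simulate, points, rng)
    state.pool.age_all()
    state.pool.add(points, counts, block)
    X, Y, W = state.pool.design(settings.w)
    surr = _fit_with_exposure(simulate, X, Y, weights=W)
    estimate, score = maximize_in_block(surr, observed_S, block, x0=state.estimate)
    state.estimate = estimate
    state.pool.purge(estimate)
    state.history.append(score)
    state.step += 1
    state.update_best(estimate, score, settings.n_b)
    logger.info("step %d: score=%.3f pool=%d estimate=%s",
                state.step, score, state.pool.size,
                np.round(np.exp(estimate), 4))
    return state


def _stopped(history: list[float], settings: SearchSettings) -> bool:
    if len(history) < settings.t_stop + 1:
        return False
    recent = history[-(settings.t_stop + 1):]
    return all(abs(recent[i + 1] - recent[i]) <= settings.epsilon
               for i in range(settings.t_stop))


def refined_search(start: np.ndarray, model: ModelSpec, simulate,
                   settings: SearchSettings, observed_S: np.ndarray,
                   rng: np.random.Generator
                   ) -> tuple[list[tuple[np.ndarray, float]], bool]:
    """Iterate steps from a start point; returns (best list, converged)."""
    state = _SearchState(estimate=np.asarray(start, dtype=float), pool=SimPool())
    converged = False
    while state.step < settings.t_max:
        jaatha_step(state, model, simulate, settings, observed_S, rng)
        if _stopped(state.history, settings):
            converged = True
            break
    return state.best, converged


def run_estimation(model: ModelSpec, simulate, settings: SearchSettings,
                   observed_S: np.ndarray, seed: int,
                   simulate_final=None, starts=None,
                   final_zero_mean: str = "neg_inf") -> EstimationResult:
    """Full two-phase estimation; deterministic given the seed.

    ``simulate_final`` (default: ``simulate``) is used for the s_final
    evaluation simulations; passing an unscaled simulator here is advisable
    when the search itself runs on exposure-scaled simulations.  ``starts``
    replaces the initial coarse search with explicit log-scale starting
    points (e.g. warm starts when refitting data simulated at a known point).
    """
    observed_S = np.asarray(observed_S, dtype=float)
    if simulate_final is None:
        simulate_final = simulate
    master = np.random.SeedSequence(seed)
    rng_init, rng_refine, rng_final = (
        np.random.default_rng(s) for s in master.spawn(3))
    if starts is None:
        starts = initial_search(model, simulate, settings, observed_S, rng_init)
    else:
        starts = [model.clip(np.asarray(s, dtype=float)) for s in starts]
    candidates: list[dict] = []
    all_converged = True
    failures = 0
    for b, start in enumerate(starts):
        try:
            best, converged = refined_search(
                start, model, simulate, settings, observed_S, rng_refine)
        except Exception as err:
            logger.warning("refined search from start %d failed: %s", b, err)
            failures += 1
            continue
        all_converged &= converged
        # the start itself is a candidate: it is the best known point when
        # warm-starting, and costs one extra evaluation otherwise
        candidates_b = [np.asarray(start, dtype=float)] + [p for p, _ in best]
        winner, winner_ll = None, -np.inf
        for point in candidates_b:
            ll = final_composite_loglik(
                simulate_final, point, settings.s_final, observed_S, rng_final,
                zero_mean=final_zero_mean)
            if ll > winner_ll or winner is None:
                winner, winner_ll = point, ll
        candidates.append({
            "start_index": b,
            "point": winner,
            "params": model.resolve(winner),
            "loglik": winner_ll,
            "converged": converged,
        })
    if not candidates:
        raise RuntimeError(f"all {failures} refined searches failed")
    best = max(candidates, key=lambda c: (c["loglik"], -c["start_index"]))
    return EstimationResult(
        model_name=model.name, param_names=list(model.free),
        best_point=best["point"],
        best_params={p: best["params"][p] for p in model.free},
        best_loglik=best["loglik"], candidates=candidates,
        converged=all_converged, seed=seed, settings=asdict(settings))


def estimate_theta_ext(model: ModelSpec, locus_config: LocusConfig,
                       settings: SearchSettings, observed_S: np.ndarray,
                       seed: int, partition: Partition | None = None,
                       fsm_config: FiniteSitesConfig | None = None,
                       theta_fix: float = 5.0
                       ) -> tuple[float, EstimationResult]:
    """Estimation with theta excluded from the search (the ext_theta option).

    All simulations run with theta fixed (default 5); theta is then
    estimated separately from the linearity of the expected total SNP count
    in theta under infinite sites:
    ``theta_hat = theta_fix * observed_total / expected_total``.
    """
    if "theta" not in model.free:
        raise ValueError("ext_theta requires a model with free theta")
    if fsm_config is not None:
        warnings.warn("ext_theta relies on an infinite-sites heuristic; "
                      "its use with finite-sites simulation is not supported "
                      "and results may be biased")
    reduced = model.with_fixed(theta=theta_fix)
    simulate = DatasetSimulator(reduced, locus_config, partition, fsm_config)
    observed_S = np.asarray(observed_S, dtype=float)
    result = run_estimation(reduced, simulate, settings, observed_S, seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    sims = np.array([simulate(result.best_point, rng)
                     for _ in range(settings.s_final)], dtype=float)
    expected_total = simulate.count_scale * sims.sum(axis=1).mean()
    if expected_total <= 0:
        raise ValueError("expected total SNP count at the fitted point is zero")
    theta_hat = theta_fix * observed_S.sum() / expected_total
    result.best_params = dict(result.best_params, theta=float(theta_hat))
    return float(theta_hat), result
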