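"""Two-population demographic models and their parameter spaces.

The basic model is an isolation-with-migration scenario: an ancestral
population of relative size ``s1 + s2`` splits ``tau`` (in units of 4*N1
generations) ago into populations P1 and P2.  P1 changes size exponentially
from ``s1*N1`` at the split to ``N1`` today; P2 from ``s2*N1`` to ``q*N1``.
A symmetric migration rate ``m`` (scaled by 4*N1, ms convention) connects the
populations.  The population mutation rate is ``theta = 4*N1*mu`` per locus.

Named models fix or constrain subsets of these parameters; the
"DecreasingMigration" model replaces ``tau`` by two spans ``tau_m`` (gene
flow present) and ``tau_0`` (no gene flow) with the migration rate halving at
the midpoint of the ``tau_m`` span.

All free parameters are handled on natural-log scale: search and surrogate
fitting operate on log-parameters, and parameter ranges are log-ranges.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DemographyParams",
    "ModelSpec",
    "DEFAULT_RANGES",
    "NAMED_MODELS",
    "build_named_model",
    "migration_epochs",
    "scale_to_natural_units",
]

#: Default natural-scale parameter ranges.  theta follows the per-locus
#: convention (1.25 to 125 per locus); the others bracket all published
#: two-population estimates for this model family and are user-overridable.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "theta": (1.25, 125.0),
    "q": (0.05, 20.0),
    "tau": (0.01, 5.0),
    "m": (0.01, 5.0),
    "s1": (0.05, 20.0),
    "s2": (0.05, 20.0),
    "tau_0": (0.005, 5.0),
    "tau_m": (0.01, 5.0),
    "alpha": (0.1, 10.0),
}


@dataclass(frozen=True)
class DemographyParams:
    """A fully resolved parameter combination of the basic model.

    ``tau_0``/``tau_m`` are only set for the DecreasingMigration model, in
    which case ``tau == tau_0 + tau_m``.
    """

    theta: float
    tau: float
    q: float
    m: float = 0.0
    s1: float = 1.0
    s2: float | None = None
    tau_0: float | None = None
    tau_m: float | None = None

    def __post_init__(self):
        s2 = self.q if self.s2 is None else self.s2
        object.__setattr__(self, "s2", s2)
        for name in ("theta", "q", "s1", "s2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.tau < 0 or self.m < 0:
            raise ValueError("tau and m must be >= 0")
        if (self.tau_0 is None) != (self.tau_m is None):
            raise ValueError("tau_0 and tau_m must be given together")
        if self.tau_0 is not None:
            if self.tau_0 < 0 or self.tau_m < 0:
                raise ValueError("tau_0 and tau_m must be >= 0")
            if not math.isclose(self.tau, self.tau_0 + self.tau_m, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError("tau must equal tau_0 + tau_m")

    @property
    def ancestral_size_ratio(self) -> float:
        return self.s1 + self.s2


@dataclass
class ModelSpec:
    """A named demographic model: free parameters with log-ranges, fixed
    parameters, and equality constraints (e.g. ``s2 = q`` in "Constant")."""

    name: str
    free: list[str]
    log_ranges: dict[str, tuple[float, float]]
    fixed: dict[str, float] = field(default_factory=dict)
    constraints: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        free_set = set(self.free)
        if len(free_set) != len(self.free):
            raise ValueError("duplicate free parameter names")
        overlap = free_set & (set(self.fixed) | set(self.constraints))
        if overlap:
            raise ValueError(f"parameters both free and fixed/constrained: {sorted(overlap)}")
        for p in self.free:
            lo, hi = self.log_ranges[p]
            if not lo < hi:
                raise ValueError(f"log-range for {p} must have min < max, got {(lo, hi)}")

    # -- geometry of the log-parameter space ---------------------------------

    @property
    def n_params(self) -> int:
        return len(self.free)

    @property
    def log_bounds(self) -> np.ndarray:
        """(n, 2) array of [ln p_min, ln p_max] in ``free`` order."""
        return np.array([self.log_ranges[p] for p in self.free], dtype=float)

    def contains(self, point: np.ndarray, atol: float = 1e-9) -> bool:
        b = self.log_bounds
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= b[:, 0] - atol) and np.all(p <= b[:, 1] + atol))

    def clip(self, point: np.ndarray) -> np.ndarray:
        b = self.log_bounds
        return np.clip(np.asarray(point, dtype=float), b[:, 0], b[:, 1])

    def sample_uniform(self, rng: np.random.Generator, size: int,
                       bounds: np.ndarray | None = None) -> np.ndarray:
        """Draw ``size`` points uniformly on log scale within ``bounds``
        (default: the full model ranges).  Returns (size, n) array."""
        b = self.log_bounds if bounds is None else np.asarray(bounds, dtype=float)
        return rng.uniform(b[:, 0], b[:, 1], size=(size, self.n_params))

    # -- resolving points into parameter combinations ------------------------

    def resolve(self, point: np.ndarray) -> dict[str, float]:
        """Map a log-scale free-parameter point to the full natural-scale
        parameter dictionary (free + fixed + constrained)."""
        p = np.asarray(point, dtype=float)
        if p.shape != (self.n_params,):
            raise ValueError(f"expected point of length {self.n_params}, got shape {p.shape}")
        values = {name: float(np.exp(v)) for name, v in zip(self.free, p)}
        values.update(self.fixed)
        for target, source in self.constraints.items():
            values[target] = values[source]
        return values

    def to_demography_params(self, point: np.ndarray) -> DemographyParams:
        values = self.resolve(point)
        values.pop("alpha", None)  # FSM nuisance parameter, not demography
        if "tau_0" in values or "tau_m" in values:
            values["tau"] = values["tau_0"] + values["tau_m"]
        return DemographyParams(**values)

    def natural_point(self, values: dict[str, float]) -> np.ndarray:
        """Log-scale point from a dict of natural-scale free values."""
        return np.log([values[p] for p in self.free])

    # -- derived models -------------------------------------------------------

    def with_fixed(self, **fixed_values: float) -> "ModelSpec":
        """A copy of this model with some free parameters fixed to values."""
        unknown = set(fixed_values) - set(self.free)
        if unknown:
            raise ValueError(f"cannot fix non-free parameters: {sorted(unknown)}")
        free = [p for p in self.free if p not in fixed_values]
        fixed = dict(self.fixed, **fixed_values)
        return replace(self, free=free, fixed=fixed,
                       log_ranges={p: self.log_ranges[p] for p in free})

    # -- serialization --------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name,
            "free": list(self.free),
            "log_ranges": {p: list(r) for p, r in self.log_ranges.items()},
            "fixed": self.fixed,
            "constraints": self.constraints,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        return cls(name=d["name"], free=list(d["free"]),
                   log_ranges={p: tuple(r) for p, r in d["log_ranges"].items()},
                   fixed=dict(d.get("fixed", {})),
                   constraints=dict(d.get("constraints", {})))


#: Free/fixed/constraint structure of the named models.
NAMED_MODELS: dict[str, dict] = {
    "Constant": {
        "free": ["theta", "q", "tau", "m"],
        "fixed": {"s1": 1.0},
        "constraints": {"s2": "q"},
    },
    "Fraction-Growth": {
        "free": ["theta", "q", "tau", "m"],
        "fixed": {"s1": 1.0, "s2": 0.05},
    },
    "NoMig": {
        "free": ["theta", "q", "tau"],
        "fixed": {"m": 0.0, "s1": 1.0, "s2": 0.3},
    },
    "FixedS2": {
        "free": ["theta", "q", "tau", "m"],
        "fixed": {"s1": 1.0, "s2": 0.3},
    },
    "SingleGrowMig": {
        "free": ["theta", "q", "tau", "m", "s2"],
        "fixed": {"s1": 1.0},
    },
    "BothGrowNoMig": {
        "free": ["theta", "q", "tau", "s1", "s2"],
        "fixed": {"m": 0.0},
    },
    "BothGrowMig": {
        "free": ["theta", "q", "tau", "m", "s1", "s2"],
        "fixed": {},
    },
    "DecreasingMigration": {
        "free": ["theta", "q", "tau_m", "tau_0", "m", "s1", "s2"],
        "fixed": {},
    },
}


def build_named_model(name: str, ranges: dict[str, tuple[float, float]] | None = None,
                      with_alpha: bool = False) -> ModelSpec:
    """Construct a :class:`ModelSpec` for one of the named nested models.

    Parameters
    ----------
    name
        One of ``NAMED_MODELS`` (e.g. "Constant", "NoMig", "FixedS2",
        "DecreasingMigration").
    ranges
        Optional natural-scale range overrides per parameter.
    with_alpha
        Add the Gamma shape parameter ``alpha`` of the finite-sites mutation
        model as a free parameter (the "+Gamma" model variants).
    """
    if name not in NAMED_MODELS:
        raise ValueError(
            f"unknown model {name!r}; valid names: {sorted(NAMED_MODELS)}")
    entry = NAMED_MODELS[name]
    free = list(entry["free"])
    if with_alpha:
        free.append("alpha")
    nat = dict(DEFAULT_RANGES)
    if ranges:
        nat.update(ranges)
    log_ranges = {p: (math.log(nat[p][0]), math.log(nat[p][1])) for p in free}
    return ModelSpec(name=name + ("+Gamma" if with_alpha else ""), free=free,
                     log_ranges=log_ranges, fixed=dict(entry["fixed"]),
                     constraints=dict(entry.get("constraints", {})))


def migration_epochs(params: DemographyParams) -> tuple[list[tuple[float, float, float]], float]:
    """Backwards-in-time migration epochs of the DecreasingMigration model.

    Returns ``(epochs, split_time)`` where each epoch is
    ``(start, end, rate)`` with times before present in 4*N1 generations:
    no migration on ``[0, tau_0)``, rate ``m/2`` on
    ``[tau_0, tau_0 + tau_m/2)`` and the full rate ``m`` from there to the
    split at ``tau_0 + tau_m``.
    """
    if params.tau_0 is None or params.tau_m is None:
        raise ValueError("migration_epochs requires a DecreasingMigration parameter set")
    t0, tm, m = params.tau_0, params.tau_m, params.m
    if t0 < 0 or tm < 0:
        raise ValueError("negative time spans")
    split = t0 + tm
    epochs: list[tuple[float, float, float]] = []
    if t0 > 0:
        epochs.append((0.0, t0, 0.0))
    if tm > 0:
        epochs.append((t0, t0 + tm / 2.0, m / 2.0))
        epochs.append((t0 + tm / 2.0, split, m))
    if not epochs:
        epochs.append((0.0, 0.0, 0.0))
    return epochs, split


def scale_to_natural_units(theta_site: float, mu_per_site: float,
                           tau: float | None = None, generation_time: float = 1.0,
                           theta_scaling: float = 4.0) -> tuple[float, float | None]:
    """Convert scaled estimates into an effective population size and a split
    time in years.

    ``theta_scaling`` is the model's convention: 4 for ``theta = 4*N1*mu``
    with ``tau`` in 4*N1 generations (ms scaling), 2 for ``theta = 2*Ne*mu``
    with ``tau`` in 2*Ne generations.  Returns ``(N_effective,
    split_time_years)``; the split time is ``None`` when ``tau`` is not given.
    """
    if theta_site <= 0 or mu_per_site <= 0 or generation_time <= 0:
        raise ValueError("inputs must be > 0")
    if theta_scaling not in (2.0, 4.0, 2, 4):
        raise ValueError("theta_scaling must be 2 or 4")
    n_eff = theta_site / (theta_scaling * mu_per_site)
    split_years = None
    if tau is not None:
        if tau <= 0:
            raise ValueError("tau must be > 0")
        split_years = tau * theta_scaling * n_eff * generation_time
    return n_eff, split_years
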