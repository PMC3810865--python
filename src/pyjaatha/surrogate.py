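"""Poisson-GLM surrogate likelihoods for the summary statistics.

Treating the summary statistics S_i as independent Poisson variables (the
composite-likelihood assumption of unlinked SNPs), their expectations are
approximated locally by log-linear models in the log-parameters,

    lambda_i(p) = exp(beta_i0 + sum_j beta_ij p_j),

fitted by maximum likelihood to simulated (point, S) pairs.  The composite
log-likelihood

    l(p) = sum_i [ -lambda_i + S_i log lambda_i - log S_i! ]

is then concave in p (a sum of -exp(linear) and linear terms), so the
within-block maximizer found by box-constrained quasi-Newton search (L-BFGS-B)
is unique up to boundary effects.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

__all__ = [
    "GlmSurrogate",
    "Block",
    "composite_loglik",
    "fit_surrogate",
    "maximize_in_block",
    "final_composite_loglik",
]

_INTERCEPT_CAP = 50.0  # natural-log cap to avoid overflow in degenerate fits


def composite_loglik(S, lam) -> float:
    """Sum of Poisson log-pmfs of observed statistics S at means lambda.

    A statistic with ``lambda_i = 0`` but ``S_i > 0`` is impossible under
    the model, so the score is -inf (data that do not conform to the model,
    e.g. multiple-hit-driven bins under infinite sites).
    """
    S = np.asarray(S, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if S.shape != lam.shape:
        raise ValueError("S and lambda must have the same length")
    if np.any(S < 0) or np.any(lam < 0):
        raise ValueError("S and lambda must be non-negative")
    zero = lam == 0
    if np.any(zero & (S > 0)):
        return float("-inf")
    ll = np.zeros_like(S)
    nz = ~zero
    ll[nz] = -lam[nz] + S[nz] * np.log(lam[nz]) - gammaln(S[nz] + 1.0)
    return float(ll.sum())


@dataclass
class Block:
    """A hypercube in log-parameter space: center +/- half_width, clipped to
    the model's log-ranges."""

    bounds: np.ndarray  # (n, 2)

    @classmethod
    def around(cls, center: np.ndarray, half_width: float,
               model_bounds: np.ndarray) -> "Block":
        center = np.asarray(center, dtype=float)
        lo = np.maximum(center - half_width, model_bounds[:, 0])
        hi = np.minimum(center + half_width, model_bounds[:, 1])
        if np.any(lo >= hi):
            raise ValueError("block has empty interior after clipping")
        return cls(bounds=np.column_stack([lo, hi]))

    @property
    def center(self) -> np.ndarray:
        return self.bounds.mean(axis=1)

    def contains(self, point: np.ndarray, atol: float = 1e-9) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= self.bounds[:, 0] - atol)
                    and np.all(p <= self.bounds[:, 1] + atol))

    def corners(self) -> np.ndarray:
        """The 2^n corner points of the block."""
        return np.array(list(itertools.product(*self.bounds)), dtype=float)


@dataclass
class GlmSurrogate:
    """Per-statistic log-linear Poisson surrogates.

    ``coef`` has shape (n_stats, 1 + n_params): intercept then slopes in
    log-parameters.
    """

    coef: np.ndarray

    @property
    def n_params(self) -> int:
        return self.coef.shape[1] - 1

    def predict(self, point: np.ndarray) -> np.ndarray:
        """Expected statistics lambda_i at a log-parameter point."""
        eta = self.coef[:, 0] + self.coef[:, 1:] @ np.asarray(point, dtype=float)
        return np.exp(np.clip(eta, -700.0, 700.0))

    def to_json(self) -> str:
        return json.dumps({"coef": self.coef.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "GlmSurrogate":
        return cls(coef=np.asarray(json.loads(text)["coef"], dtype=float))


def _intercept_only(y: np.ndarray, w: np.ndarray, n_params: int) -> np.ndarray:
    mean = float(np.average(y, weights=w))
    intercept = -_INTERCEPT_CAP if mean <= 0 else np.clip(
        np.log(mean), -_INTERCEPT_CAP, _INTERCEPT_CAP)
    return np.concatenate([[intercept], np.zeros(n_params)])


def _batched_poisson_irls(X: np.ndarray, Y: np.ndarray, w: np.ndarray,
                          max_iter: int = 60, tol: float = 1e-9) -> np.ndarray:
    """Weighted Poisson ML with log link for many responses sharing one
    design matrix, via iteratively reweighted least squares.

    Returns the (n_stats, p) coefficient matrix; rows that fail to converge
    or run away (separation) are NaN.
    """
    n_obs, p = X.shape
    n_stats = Y.shape[1]
    beta = np.zeros((n_stats, p))
    mean0 = np.average(Y, axis=0, weights=w)
    beta[:, 0] = np.log(np.maximum(mean0, 1e-12))
    active = np.ones(n_stats, dtype=bool)
    ridge = 1e-10 * np.eye(p)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = np.clip(X @ beta[active].T, -_INTERCEPT_CAP, _INTERCEPT_CAP)
        mu = np.exp(eta)
        W = w[:, None] * mu                              # (n_obs, k)
        z = eta + (Y[:, active] - mu) / mu               # working response
        A = np.einsum("np,nk,nq->kpq", X, W, X) + ridge
        b = np.einsum("np,nk,nk->kp", X, W, z)
        try:
            new = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta[active] = np.nan
            break
        delta = np.abs(new - beta[active]).max(axis=1)
        bad = ~np.isfinite(new).all(axis=1) | (np.abs(new).max(axis=1) > 1e3)
        beta[active] = np.where(bad[:, None], np.nan, new)
        still = active.copy()
        still[active] = ~bad & (delta > tol)
        active = still
    if active.any():  # hit max_iter without settling
        beta[active] = np.nan
    return beta


def fit_surrogate(points: np.ndarray, counts: np.ndarray,
                  weights: np.ndarray | None = None) -> GlmSurrogate:
    """Fit Poisson GLMs (log link, main effects in log-parameters) to every
    summary statistic.

    ``points`` is (N, n_params) on log scale; ``counts`` is (N, n_stats);
    ``weights`` are per-observation likelihood weights (the w^age scheme).
    All statistics share the design matrix, so the fits run through one
    batched IRLS solver (equivalent to per-statistic weighted Poisson ML;
    cross-checked against statsmodels GLM in the test suite).  Statistics
    whose fit does not converge (e.g. separation) fall back to a capped
    intercept-only model with a warning.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    n_obs, n_params = points.shape
    if counts.shape[0] != n_obs:
        raise ValueError("points and counts disagree on the number of simulations")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if n_obs < n_params + 1:
        raise ValueError(
            f"need at least n_params+1 = {n_params + 1} simulations, got {n_obs}")
    w = np.ones(n_obs) if weights is None else np.asarray(weights, dtype=float)
    X = np.column_stack([np.ones(n_obs), points])
    coef = np.empty((counts.shape[1], n_params + 1))
    nonzero = counts.max(axis=0) > 0
    coef[~nonzero] = [_intercept_only(counts[:, i], w, n_params)
                      for i in np.nonzero(~nonzero)[0]] if (~nonzero).any() else 0.0
    if nonzero.any():
        beta = _batched_poisson_irls(X, counts[:, nonzero], w)
        failed = ~np.isfinite(beta).all(axis=1)
        if failed.any():
            warnings.warn(
                f"{failed.sum()} Poisson GLM fit(s) did not converge; "
                "falling back to intercept-only models")
            idx = np.nonzero(nonzero)[0][failed]
            beta[failed] = [_intercept_only(counts[:, i], w, n_params) for i in idx]
        beta[:, 0] = np.clip(beta[:, 0], -_INTERCEPT_CAP, _INTERCEPT_CAP)
        coef[nonzero] = beta
    return GlmSurrogate(coef=coef)


def _neg_obj(p, coef, S):
    eta = coef[:, 0] + coef[:, 1:] @ p
    lam = np.exp(np.clip(eta, -700.0, 700.0))
    ll = np.sum(-lam + S * eta)  # gammaln term constant in p
    grad = coef[:, 1:].T @ (S - lam)
    return -ll, -grad


def maximize_in_block(surrogate: GlmSurrogate, S_observed: np.ndarray,
                      block: Block, x0: np.ndarray | None = None
                      ) -> tuple[np.ndarray, float]:
    """Maximize the surrogate composite log-likelihood over a block.

    Returns ``(point, score)`` with the score being the full composite
    log-likelihood (including the log-factorial terms).  Falls back to
    multi-start from the block corners if the first optimization fails.
    """
    S = np.asarray(S_observed, dtype=float)
    coef = surrogate.coef
    bounds = [tuple(b) for b in block.bounds]
    starts = [block.center if x0 is None else np.asarray(x0, dtype=float)]
    best = None
    for attempt, start in enumerate(starts):
        res = minimize(_neg_obj, start, args=(coef, S), jac=True,
                       method="L-BFGS-B", bounds=bounds)
        if res.success and (best is None or res.fun < best.fun):
            best = res
        if best is None and attempt == len(starts) - 1 and len(starts) == 1:
            starts.extend(list(block.corners()))  # multi-start fallback
    if best is None:
        raise RuntimeError("block maximization failed from every start point")
    point = np.asarray(best.x, dtype=float)
    return point, composite_loglik(S, surrogate.predict(point))


def final_composite_loglik(simulate, point: np.ndarray, s_final: int,
                           observed_S: np.ndarray, rng: np.random.Generator,
                           zero_mean: str = "neg_inf") -> float:
    """Simulation-based composite log-likelihood at a parameter point.

    ``lambda_i`` is estimated by the mean of S_i over ``s_final`` fresh
    simulations at ``point`` (``simulate(point, rng) -> S``).  By default a
    statistic observed but never simulated yields -inf (data the model
    cannot produce).  Under a finite-sites model every class has positive
    probability, so there a zero simulated mean is a Monte-Carlo artifact;
    ``zero_mean="floor"`` replaces it by the half-pseudocount value
    0.5/s_final (on the observed-count scale).  A simulator carrying a
    ``count_scale`` exposure attribute (fewer simulated than observed loci)
    has its means rescaled accordingly.
    """
    if s_final < 1:
        raise ValueError("s_final must be >= 1")
    if zero_mean not in ("neg_inf", "floor"):
        raise ValueError("zero_mean must be 'neg_inf' or 'floor'")
    sims = np.array([simulate(point, rng) for _ in range(s_final)], dtype=float)
    scale = getattr(simulate, "count_scale", 1.0)
    lam = scale * sims.mean(axis=0)
    if zero_mean == "floor":
        lam = np.maximum(lam, scale * 0.5 / s_final)
    return composite_loglik(observed_S, lam)
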