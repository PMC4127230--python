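"""Coordinate-descent core for penalized least squares in Gram form.

Every sparse subproblem in this package is an instance of

    minimize_theta  ||y - theta D||^2  +  sum_j t_j |theta_j|

for a stacked regressor matrix ``D`` (rows = regressors, columns = samples)
and per-coordinate penalty levels ``t_j`` (a bare lasso uses a constant
``t_j = lambda``; the adaptive lasso uses ``t_j = w_j * lambda``). Writing
``G = D D^T`` and ``d = D y^T``, the exact single-coordinate minimizer is a
soft-threshold step

    theta_j <- soft(c_j, t_j / 2) / G_jj,   c_j = d_j - sum_{k != j} G_jk theta_k

(the half-threshold comes from the squared-loss convention without a 1/2
factor). Coordinates may be frozen at zero (infinite penalty weight) via an
active mask; frozen coordinates are never touched, which is how "a zeroed
coefficient can never come back" is enforced structurally.

The sweep loop is JIT-compiled with numba; a thin Python wrapper offers an
objective-per-sweep recording mode used by the monotonicity tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


@njit(cache=True)
def _cd_sweeps(G, d, thr, theta, active, tol, max_sweeps):  # pragma: no cover - jitted
    p = theta.shape[0]
    n_sweeps = 0
    for _ in range(max_sweeps):
        n_sweeps += 1
        max_delta = 0.0
        for j in range(p):
            if not active[j]:
                continue
            gjj = G[j, j]
            if gjj <= 0.0:
                new = 0.0
            else:
                cj = d[j] + gjj * theta[j]
                for k in range(p):
                    cj -= G[j, k] * theta[k]
                half = 0.5 * thr[j]
                if cj > half:
                    new = (cj - half) / gjj
                elif cj < -half:
                    new = (cj + half) / gjj
                else:
                    new = 0.0
            delta = abs(new - theta[j])
            if delta > max_delta:
                max_delta = delta
            theta[j] = new
        if max_delta < tol:
            return n_sweeps, True
    return n_sweeps, False


def quadratic_l1_objective(
    G: np.ndarray, d: np.ndarray, yty: float, thr: np.ndarray, theta: np.ndarray
) -> float:
    """Value of ||y - theta D||^2 + sum_j t_j |theta_j| in Gram form."""
    finite = np.isfinite(thr) | (theta == 0.0)
    if not finite.all():
        return np.inf
    pen = float(np.sum(np.where(theta == 0.0, 0.0, thr) * np.abs(theta)))
    return float(theta @ G @ theta - 2.0 * d @ theta + yty + pen)


@dataclass
class CdSolution:
    """Result of a coordinate-descent solve."""

    theta: np.ndarray
    objective: float
    sweeps: int
    converged: bool
    objective_history: np.ndarray | None = None


def solve_quadratic_l1(
    G: np.ndarray,
    d: np.ndarray,
    yty: float,
    thresholds: np.ndarray,
    theta0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
    record_objective: bool = False,
) -> CdSolution:
    """Minimize ``||y - theta D||^2 + sum_j t_j |theta_j|`` by coordinate descent.

    Parameters
    ----------
    G, d, yty
        Gram matrix ``D D^T``, linear term ``D y^T``, and ``y y^T``.
    thresholds
        Per-coordinate penalty levels ``t_j >= 0``; ``inf`` freezes the
        coordinate at zero permanently.
    theta0
        Warm start (copied); frozen coordinates are forced to zero.
    record_objective
        When true, the objective value after every sweep is recorded (the
        solver then advances one sweep per kernel call, trading speed for
        the history used in monotonicity checks).
    """
    G = np.ascontiguousarray(G, dtype=np.float64)
    d = np.ascontiguousarray(d, dtype=np.float64)
    thr = np.asarray(thresholds, dtype=np.float64)
    if thr.shape != d.shape or G.shape != (d.size, d.size):
        raise ValueError("inconsistent Gram-system shapes")
    if np.any(thr < 0):
        raise ValueError("penalty thresholds must be non-negative")
    active = np.isfinite(thr)
    theta = np.zeros_like(d) if theta0 is None else np.array(theta0, dtype=np.float64)
    theta[~active] = 0.0
    thr_finite = np.where(active, thr, 0.0)

    if not record_objective:
        sweeps, converged = _cd_sweeps(G, d, thr_finite, theta, active, tol, max_sweeps)
        obj = quadratic_l1_objective(G, d, yty, thr_finite, theta)
        return CdSolution(theta, obj, int(sweeps), bool(converged))

    history = []
    total = 0
    converged = False
    while total < max_sweeps and not converged:
        _, converged = _cd_sweeps(G, d, thr_finite, theta, active, tol, 1)
        total += 1
        history.append(quadratic_l1_objective(G, d, yty, thr_finite, theta))
    obj = history[-1] if history else quadratic_l1_objective(G, d, yty, thr_finite, theta)
    return CdSolution(theta, obj, total, bool(converged), np.asarray(history))


def penalty_upper_bound(d: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Smallest constant penalty level at which the all-zero vector is optimal.

    For the objective above, ``theta = 0`` is stationary iff
    ``t_j >= 2 |d_j|`` for every coordinate, so a path started at this value
    begins from the empty model.
    """
    d = np.asarray(d, dtype=float)
    if weights is None:
        return 2.0 * float(np.max(np.abs(d), initial=0.0))
    w = np.asarray(weights, dtype=float)
    finite = np.isfinite(w) & (w > 0)
    if not finite.any():
        return 0.0
    return 2.0 * float(np.max(np.abs(d[finite]) / w[finite]))
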