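"""Independent solvers used as cross-checks in the test suite.

``solve_penalized_ls`` minimizes

    ||y - theta D||^2 + sum_j q_j theta_j^2 + sum_j t_j |theta_j|

with a generic smooth optimizer (L-BFGS-B) on the split-variable
reformulation theta = u - v, u, v >= 0, under which the ell1 term becomes
the linear form sum t_j (u_j + v_j) and the problem is an exactly smooth
bound-constrained convex program. It shares no code with the package's
coordinate-descent solver.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def penalized_objective(
    D: np.ndarray,
    y: np.ndarray,
    theta: np.ndarray,
    ridge: np.ndarray | None = None,
    l1: np.ndarray | None = None,
) -> float:
    r = y - theta @ D
    val = float(r @ r)
    if ridge is not None:
        val += float(np.sum(ridge * theta**2))
    if l1 is not None:
        pen = np.where(theta == 0.0, 0.0, l1)
        val += float(np.sum(pen * np.abs(theta)))
    return val


def solve_penalized_ls(
    D: np.ndarray,
    y: np.ndarray,
    ridge: np.ndarray | None = None,
    l1: np.ndarray | None = None,
    tol: float = 1e-14,
) -> tuple[np.ndarray, float]:
    """Minimize the mixed-penalty least squares above; returns (theta, objective).

    Coordinates with an infinite ell1 weight are excluded from the program
    (fixed at zero).
    """
    p = D.shape[0]
    ridge = np.zeros(p) if ridge is None else np.asarray(ridge, float)
    l1 = np.zeros(p) if l1 is None else np.asarray(l1, float)
    free = np.isfinite(l1)
    Df = D[free]
    qf = ridge[free]
    tf = l1[free]
    k = Df.shape[0]
    if k == 0:
        theta = np.zeros(p)
        return theta, penalized_objective(D, y, theta, ridge, l1)

    G = Df @ Df.T
    d = Df @ y
    yty = float(y @ y)

    def fun(z):
        u, v = z[:k], z[k:]
        th = u - v
        grad_smooth = 2.0 * (G @ th + qf * th - d)
        val = th @ G @ th - 2.0 * d @ th + yty + qf @ th**2 + tf @ (u + v)
        return val, np.concatenate([grad_smooth + tf, -grad_smooth + tf])

    z0 = np.zeros(2 * k)
    res = minimize(
        fun, z0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * k),
        options={"maxiter": 20_000, "ftol": tol, "gtol": 1e-12},
    )
    th = res.x[:k] - res.x[k:]
    theta = np.zeros(p)
    theta[free] = th
    return theta, penalized_objective(D, y, theta, ridge, l1)
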