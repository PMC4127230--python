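"""Weighted-ell1 (adaptive lasso) solver for one gene's SEM row.

The adaptive lasso re-penalizes each coefficient by the inverse magnitude of
a previous estimate:

    min_{b_i, f_i} ||y_i - b_i Y - f_i X||^2
                   + lambda1 sum_j w^b_ij |b_ij| + lambda2 sum_j w^f_ij |f_ij|,

    w^b_ij = |b_hat_ij|^-alpha,   w^f_ij = |f_hat_ij|^-beta.

Coefficients whose previous estimate is zero receive an infinite weight and
are frozen at zero permanently — a pruned edge can never return, which is
what makes iterating the procedure a strictly monotone edge filter. The
exponents alpha and beta set how strongly previous magnitudes steer the
next fit; alpha = 0 (or beta = 0) is the special case of unit weights on
surviving coefficients and infinite weights on pruned ones.

Infinite weights are represented by a frozen-coordinate mask inside the
solver, never by arithmetic on ``inf``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._solvers import CdSolution, solve_quadratic_l1
from .datatypes import DEFAULT_ZERO_TOL, InvalidInputError


@dataclass
class PenaltyWeights:
    """Per-coordinate adaptive penalty weights for one gene row."""

    w_b: np.ndarray
    w_f: np.ndarray
    alpha: float
    beta: float


def make_weights(
    b_hat: np.ndarray,
    f_hat: np.ndarray,
    alpha: float,
    beta: float,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> PenaltyWeights:
    """Adaptive weights from previous estimates.

    Nonzero estimates get ``|est|^-alpha`` (unit weight when the exponent is
    0); zero estimates get an infinite weight, freezing the coefficient.
    """
    if alpha < 0 or beta < 0:
        raise InvalidInputError("alpha and beta must be non-negative")

    def _one(est: np.ndarray, expo: float) -> np.ndarray:
        est = np.asarray(est, dtype=float)
        w = np.full(est.shape, np.inf)
        nz = np.abs(est) > zero_tol
        w[nz] = 1.0 if expo == 0 else np.abs(est[nz]) ** (-expo)
        return w

    return PenaltyWeights(_one(b_hat, alpha), _one(f_hat, beta), alpha, beta)


def adaptive_lasso_fit_gene(
    i: int,
    Yc: np.ndarray,
    Xc: np.ndarray,
    weights: PenaltyWeights,
    lambda1: float,
    lambda2: float,
    init_b: np.ndarray | None = None,
    init_f: np.ndarray | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
    record_objective: bool = False,
) -> tuple[np.ndarray, np.ndarray, CdSolution]:
    """Joint coordinate descent over (b_i, f_i) under adaptive weights.

    Gene i's own expression row is excluded (so ``b_ii = 0`` structurally);
    the remaining gene rows and all SNP rows are stacked into one regressor
    matrix and swept in fixed ascending order, gene block first. Returns
    ``(b_i, f_i, solution)`` with ``b_i`` re-inflated to full length.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise InvalidInputError("penalty levels must be non-negative")
    m_g, m_s = Yc.shape[0], Xc.shape[0]
    if weights.w_b.shape != (m_g,) or weights.w_f.shape != (m_s,):
        raise InvalidInputError("weight vectors do not match the data dimensions")
    y = Yc[i]
    Yt = np.delete(Yc, i, axis=0)
    D = np.vstack([Yt, Xc])
    G = D @ D.T
    d = D @ y
    yty = float(y @ y)
    thr = np.concatenate(
        [lambda1 * np.delete(weights.w_b, i), lambda2 * weights.w_f]
    )
    theta0 = None
    if init_b is not None or init_f is not None:
        b0 = np.zeros(m_g) if init_b is None else np.asarray(init_b, float)
        f0 = np.zeros(m_s) if init_f is None else np.asarray(init_f, float)
        theta0 = np.concatenate([np.delete(b0, i), f0])
    sol = solve_quadratic_l1(
        G, d, yty, thr, theta0=theta0, tol=tol, max_sweeps=max_sweeps,
        record_objective=record_objective,
    )
    b = np.insert(sol.theta[: m_g - 1], i, 0.0)
    f = sol.theta[m_g - 1:]
    return b, f, sol
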