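"""SNP screening stages: ridge initialization, elastic-net candidate
selection, and lasso-path finalization of one eQTL per gene.

The inference pipeline fixes each gene's eQTL *before* the gene-gene network
is finalized, in three moves applied per target gene ``i`` (all regressions
exclude gene i's own expression row, which pins ``b_ii = 0``):

1. **Ridge** — the doubly-penalized least squares

       ||y_i - b_i Y - f_i X||^2 + lambda1 ||b_i||^2 + lambda2 ||f_i||^2

   has the closed-form joint minimizer obtained by eliminating ``b_i``:
   with ``S1 = X^T - Y^T (Y Y^T + lambda1 I)^-1 Y X^T``,

       f_i = y_i S1 (X S1 + lambda2 I)^-1,
       b_i = (y_i - f_i X) Y^T (Y Y^T + lambda1 I)^-1.

   Penalty levels are picked per gene by K-fold cross-validation.

2. **Elastic net** (ell2 on genes, ell1 on SNPs) — minimizing the ridge
   penalty over ``b_i`` in closed form collapses the problem to a lasso in
   ``f_i`` alone: with ``P = Y^T (Y Y^T + lambda1 I)^-1 Y``,

       min_b ||y - b Y - f X||^2 + lambda1 ||b||^2
           = (y - f X)(I - P)(y - f X)^T,

   so the SNP block is solved by soft-threshold coordinate descent on the
   Gram system ``G = X (I - P) X^T``, ``d = X (I - P) y^T``. SNPs with a
   nonzero coefficient are the gene's candidate eQTLs.

3. **Lasso path** — genes and surviving candidate SNPs (capped at the
   ``n_k`` largest ``|f_ij|``, default 5) are stacked into one regressor
   matrix and an ell1 path is traced from the empty model downward; the
   candidate SNP whose coefficient becomes nonzero at the largest penalty
   is declared the gene's eQTL. Gene coefficients along the path are fitted
   but never compete for the eQTL slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._solvers import CdSolution, penalty_upper_bound, solve_quadratic_l1
from .datatypes import DEFAULT_ZERO_TOL, InvalidInputError

DEFAULT_LAMBDA_GRID = np.geomspace(1e-3, 1e3, 20)
DEFAULT_TOP_K = 5


def _drop_row(M: np.ndarray, i: int) -> np.ndarray:
    return np.delete(M, i, axis=0)


def _insert_zero(v: np.ndarray, i: int) -> np.ndarray:
    return np.insert(v, i, 0.0)


def kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled K-fold test-index partition of ``range(n)``."""
    if k < 2 or n < k:
        raise InvalidInputError(f"need 2 <= k_folds <= n_samples, got k={k}, n={n}")
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


# ---------------------------------------------------------------------------
# Step 1-1: ridge


@dataclass
class RidgeSolution:
    """Dense ridge estimates of (B, F) with the per-gene penalty levels."""

    B_ridge: np.ndarray
    F_ridge: np.ndarray
    lambda1: np.ndarray
    lambda2: np.ndarray


def ridge_fit_gene(
    i: int,
    Yc: np.ndarray,
    Xc: np.ndarray,
    lambda1: float,
    lambda2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form ridge fit of gene i's row of (B, F) on centered data.

    Returns ``(b_i, f_i)`` with ``b_ii = 0`` (gene i's own expression row is
    excluded from the regressors).
    """
    if lambda1 <= 0 or lambda2 <= 0:
        raise InvalidInputError("ridge requires strictly positive penalties")
    y = Yc[i]
    Yt = _drop_row(Yc, i)
    A = Yt @ Yt.T + lambda1 * np.eye(Yt.shape[0])
    YX = Yt @ Xc.T
    Yy = Yt @ y
    T = np.linalg.solve(A, YX)
    u = np.linalg.solve(A, Yy)
    XS1 = Xc @ Xc.T - YX.T @ T          # X S1, symmetric PSD
    yS1 = Xc @ y - YX.T @ u             # y_i S1
    f = np.linalg.solve(XS1 + lambda2 * np.eye(Xc.shape[0]), yS1)
    b_sub = np.linalg.solve(A, Yy - YX @ f)
    return _insert_zero(b_sub, i), f


def ridge_cv(
    Yc: np.ndarray,
    Xc: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    k_folds: int = 5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (lambda1, lambda2) minimizing K-fold held-out squared error.

    One shared fold assignment is used for every gene and every grid point.
    Ties resolve to the smaller penalty (first grid point in ascending
    order).
    """
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    if grid.size == 0:
        raise InvalidInputError("lambda grid must be non-empty")
    rng = np.random.default_rng() if rng is None else rng
    m_g, n = Yc.shape
    m_s = Xc.shape[0]
    folds = kfold_indices(n, k_folds, rng)
    err = np.zeros((m_g, grid.size, grid.size))
    eye_s = np.eye(m_s)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Ytr, Yte = Yc[:, train_idx], Yc[:, test_idx]
        Xtr, Xte = Xc[:, train_idx], Xc[:, test_idx]
        XXtr = Xtr @ Xtr.T
        for i in range(m_g):
            y_tr, y_te = Ytr[i], Yte[i]
            Yt_tr, Yt_te = _drop_row(Ytr, i), _drop_row(Yte, i)
            YY = Yt_tr @ Yt_tr.T
            YX = Yt_tr @ Xtr.T
            Yy = Yt_tr @ y_tr
            Xy = Xtr @ y_tr
            for a, lam1 in enumerate(grid):
                A = YY + lam1 * np.eye(m_g - 1)
                T = np.linalg.solve(A, YX)
                u = np.linalg.solve(A, Yy)
                XS1 = XXtr - YX.T @ T
                yS1 = Xy - YX.T @ u
                for b, lam2 in enumerate(grid):
                    f = np.linalg.solve(XS1 + lam2 * eye_s, yS1)
                    b_sub = np.linalg.solve(A, Yy - YX @ f)
                    resid = y_te - b_sub @ Yt_te - f @ Xte
                    err[i, a, b] += resid @ resid
    lam1_idx, lam2_idx = np.unravel_index(
        err.reshape(m_g, -1).argmin(axis=1), (grid.size, grid.size)
    )
    return grid[lam1_idx], grid[lam2_idx]


def ridge_fit_all(
    Yc: np.ndarray, Xc: np.ndarray, lambda1: np.ndarray, lambda2: np.ndarray
) -> RidgeSolution:
    """Ridge fit of every gene's row at its own (lambda1, lambda2)."""
    m_g, m_s = Yc.shape[0], Xc.shape[0]
    B = np.zeros((m_g, m_g))
    F = np.zeros((m_g, m_s))
    for i in range(m_g):
        B[i], F[i] = ridge_fit_gene(i, Yc, Xc, float(lambda1[i]), float(lambda2[i]))
    return RidgeSolution(B, F, np.asarray(lambda1, float), np.asarray(lambda2, float))


# ---------------------------------------------------------------------------
# Step 1-2: elastic net


def _profiled_gram(i: int, Yc: np.ndarray, Xc: np.ndarray, lambda1: float):
    """Gram system of the b-profiled elastic-net objective for gene i."""
    y = Yc[i]
    Yt = _drop_row(Yc, i)
    A = Yt @ Yt.T + lambda1 * np.eye(Yt.shape[0])
    YX = Yt @ Xc.T
    Yy = Yt @ y
    T = np.linalg.solve(A, YX)
    u = np.linalg.solve(A, Yy)
    G = Xc @ Xc.T - YX.T @ T
    d = Xc @ y - YX.T @ u
    yty = float(y @ y - Yy @ u)
    return G, d, yty, A, YX, Yy


def elastic_net_fit_gene(
    i: int,
    Yc: np.ndarray,
    Xc: np.ndarray,
    lambda1: float,
    lambda2: float,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
    f0: np.ndarray | None = None,
    record_objective: bool = False,
) -> tuple[np.ndarray, np.ndarray, CdSolution]:
    """Coordinate-descent elastic-net fit of gene i: sparse ``f_i`` with the
    ridge-profiled ``b_i`` recovered afterwards.

    Returns ``(b_i, f_i, solution)``; ``solution.objective`` is the full
    elastic-net objective value (residual + both penalties) at the optimum.
    """
    if lambda1 <= 0 or lambda2 < 0:
        raise InvalidInputError("elastic net requires lambda1 > 0 and lambda2 >= 0")
    G, d, yty, A, YX, Yy = _profiled_gram(i, Yc, Xc, lambda1)
    thr = np.full(Xc.shape[0], float(lambda2))
    sol = solve_quadratic_l1(
        G, d, yty, thr, theta0=f0, tol=tol, max_sweeps=max_sweeps,
        record_objective=record_objective,
    )
    f = sol.theta
    b_sub = np.linalg.solve(A, Yy - YX @ f)
    return _insert_zero(b_sub, i), f, sol


def elastic_net_cv_lambda2(
    i: int,
    Yc: np.ndarray,
    Xc: np.ndarray,
    lambda1: float,
    lambda_grid: np.ndarray | None = None,
    k_folds: int = 5,
    rng: np.random.Generator | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
) -> float:
    """Pick gene i's ell1 level lambda2 by K-fold cross-validation with the
    one-standard-error rule, warm-starting down the grid.

    The screen's job is to keep only SNPs that are plausibly true eQTLs, so
    the selected lambda2 is the strongest penalty whose mean held-out error
    is within one standard error of the minimum — the usual parsimony rule
    for a screening stage (CV-minimizing lasso penalties systematically
    overselect).
    """
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    if grid.size == 0:
        raise InvalidInputError("lambda grid must be non-empty")
    rng = np.random.default_rng() if rng is None else rng
    n = Yc.shape[1]
    folds = kfold_indices(n, k_folds, rng)
    order = np.argsort(grid)[::-1]  # strongest penalty first for warm starts
    err = np.zeros((len(folds), grid.size))
    for fold, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Ytr, Yte = Yc[:, train_idx], Yc[:, test_idx]
        Xtr, Xte = Xc[:, train_idx], Xc[:, test_idx]
        f_warm = None
        for g in order:
            b, f, _ = elastic_net_fit_gene(
                i, Ytr, Xtr, lambda1, float(grid[g]), tol=tol,
                max_sweeps=max_sweeps, f0=f_warm,
            )
            f_warm = f
            resid = Yte[i] - b @ Yte - f @ Xte  # b has b_ii = 0
            err[fold, g] += resid @ resid
    mean = err.mean(axis=0)
    g_min = int(mean.argmin())
    se = err.std(axis=0, ddof=1) / np.sqrt(len(folds))
    within = np.flatnonzero(mean <= mean[g_min] + se[g_min])
    return float(grid[within[np.argmax(grid[within])]])


@dataclass
class CandidateEqtls:
    """Per-gene candidate SNP sets from the elastic-net screen.

    ``F_cand`` keeps each row's nonzero coefficients truncated to the
    ``top_k`` largest magnitudes.
    """

    F_cand: np.ndarray
    top_k: int = DEFAULT_TOP_K

    def candidates(self, i: int, zero_tol: float = DEFAULT_ZERO_TOL) -> np.ndarray:
        """Candidate SNP indices for gene i, by descending |f_ij|."""
        row = self.F_cand[i]
        nz = np.flatnonzero(np.abs(row) > zero_tol)
        return nz[np.argsort(-np.abs(row[nz]), kind="stable")]


def truncate_candidates(F_en: np.ndarray, top_k: int = DEFAULT_TOP_K,
                        zero_tol: float = DEFAULT_ZERO_TOL) -> CandidateEqtls:
    """Keep at most ``top_k`` nonzero entries per row of the elastic-net F."""
    F = np.array(F_en, dtype=float)
    for i, row in enumerate(F):
        nz = np.flatnonzero(np.abs(row) > zero_tol)
        if nz.size > top_k:
            drop = nz[np.argsort(np.abs(row[nz]))[: nz.size - top_k]]
            F[i, drop] = 0.0
    return CandidateEqtls(F, top_k)


# ---------------------------------------------------------------------------
# Step 2: lasso-path eQTL finalization


@dataclass
class EqtlAssignment:
    """Final one-SNP-per-gene assignment with entry diagnostics."""

    snp_of_gene: dict[int, int] = field(default_factory=dict)
    entry_lambda: dict[int, float] = field(default_factory=dict)
    fallback_genes: set[int] = field(default_factory=set)


def lasso_path_eqtl(
    i: int,
    Yc: np.ndarray,
    Xc: np.ndarray,
    cand: CandidateEqtls,
    n_path: int = 50,
    path_min_ratio: float = 0.01,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> tuple[int | None, float | None, bool]:
    """First-entry lasso selection of gene i's single eQTL.

    Stacks the other genes' expression rows and the candidate SNP rows into
    one regressor matrix, traces an ell1 path from the empty model downward,
    and returns ``(snp, entry_lambda, fallback)`` where ``snp`` is the
    candidate whose coefficient first becomes nonzero (ties at one path
    point break to the larger |coefficient|). When no candidate enters
    before the path floor — or the candidate set is empty — the elastic-net
    coefficient of largest magnitude is returned with ``fallback=True``
    (``snp`` is None if the gene has no candidates at all).

    Rows of the stacked design are standardized to unit variance before the
    path is traced, so entry order reflects (partial) correlation with the
    target rather than raw variance scale — expression rows carry the
    accumulated variance of their regulators and would otherwise enter far
    too eagerly, dragging their own eQTLs in behind them.
    """
    cands = cand.candidates(i, zero_tol)
    if cands.size == 0:
        return None, None, True
    if cands.size == 1:
        # single possible first entrant; no path needed
        return int(cands[0]), None, False
    y = Yc[i]
    Yt = _drop_row(Yc, i)
    Z = np.vstack([Yt, Xc[cands]])
    scale = Z.std(axis=1)
    scale[scale <= 0] = 1.0  # constant rows can never enter anyway
    Z = Z / scale[:, None]
    G = Z @ Z.T
    d = Z @ y
    yty = float(y @ y)
    lam_max = penalty_upper_bound(d)
    if lam_max <= 0:
        return int(cands[0]), None, True
    path = np.geomspace(lam_max, path_min_ratio * lam_max, n_path)
    n_gene_coords = Yt.shape[0]
    theta = np.zeros(Z.shape[0])
    for lam in path:
        thr = np.full(Z.shape[0], float(lam))
        sol = solve_quadratic_l1(G, d, yty, thr, theta0=theta, tol=tol, max_sweeps=max_sweeps)
        theta = sol.theta
        snp_coefs = theta[n_gene_coords:]
        nz = np.flatnonzero(np.abs(snp_coefs) > zero_tol)
        if nz.size:
            best = nz[np.argmax(np.abs(snp_coefs[nz]))]
            return int(cands[best]), float(lam), False
    # no candidate ever entered: fall back to the strongest screened SNP
    return int(cands[0]), None, True


def assign_eqtls(
    Yc: np.ndarray,
    Xc: np.ndarray,
    cand: CandidateEqtls,
    **path_kwargs,
) -> EqtlAssignment:
    """Run the lasso-path finalization for every gene."""
    out = EqtlAssignment()
    for i in range(Yc.shape[0]):
        snp, lam, fb = lasso_path_eqtl(i, Yc, Xc, cand, **path_kwargs)
        if snp is not None:
            out.snp_of_gene[i] = snp
        if lam is not None:
            out.entry_lambda[i] = lam
        if fb:
            out.fallback_genes.add(i)
    return out
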