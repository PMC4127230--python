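"""End-to-end SGRN inference: iterative adaptive lasso over a sparse SEM.

Two operating modes:

* **IAL2** (eQTL unknown) — the full pipeline: per-gene ridge with
  cross-validated penalties (Step 1-1), elastic-net SNP screening
  (Step 1-2), lasso-path finalization of a single candidate eQTL per gene
  (Step 2), then the iterative adaptive lasso (Step 3).
* **IAL1** (eQTL known) — Steps 1 and 2 are skipped; Step 3 runs with the
  F support fixed to a user-supplied gene -> SNP map.

Step 3 proceeds as follows. B and F are re-initialized by a *restricted*
ridge: per gene, an ell2 penalty on the gene block (level chosen by K-fold
cross-validation) and the single retained SNP fitted without penalty. The
first adaptive-lasso pass uses weights from this ridge refit; the
adaptive-lasso penalty levels are estimated once by K-fold cross-validation
before the loop starts. The outer loop then raises the weight exponent
alpha in fixed increments; at each alpha an inner loop re-runs the adaptive
lasso with weights from the previous pass until the number of selected
gene-gene edges N_e(B) stops changing. Because pruned coefficients receive
infinite weights, the B support shrinks monotonically; the outer loop
terminates when an entire inner loop makes no change in N_e(B) (or when
alpha reaches its cap, which is recorded as a distinct termination reason).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .adaptive import adaptive_lasso_fit_gene, make_weights
from .datatypes import (
    DEFAULT_ZERO_TOL,
    EqtlMatrix,
    ExpressionMatrix,
    GeneAdjacency,
    GenotypeMatrix,
    InvalidInputError,
    SgrnResult,
    support,
)
from .screening import (
    DEFAULT_LAMBDA_GRID,
    assign_eqtls,
    elastic_net_cv_lambda2,
    elastic_net_fit_gene,
    kfold_indices,
    ridge_cv,
    ridge_fit_all,
    truncate_candidates,
)

logger = logging.getLogger(__name__)

IAL1 = "ial1"
IAL2 = "ial2"


@dataclass(frozen=True)
class IalConfig:
    """Tuning knobs of the full pipeline; defaults are the reference study
    conditions (5-fold CV, 5 candidate SNPs per gene, alpha swept from 0 in
    steps of 0.5 up to 3 with beta fixed at 0.5)."""

    mode: str = IAL2
    alpha0: float = 0.0
    alpha_step: float = 0.5
    alpha_max: float = 3.0
    beta: float = 0.5
    k_folds: int = 5
    n_k: int = 5
    lambda_grid_min: float = 1e-3
    lambda_grid_max: float = 1e3
    lambda_grid_size: int = 20
    n_path: int = 50
    path_min_ratio: float = 0.01
    cd_tol: float = 1e-6
    cd_max_sweeps: int = 10_000
    max_inner: int = 50
    zero_tol: float = DEFAULT_ZERO_TOL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (IAL1, IAL2):
            raise InvalidInputError(f"mode must be '{IAL1}' or '{IAL2}', got {self.mode!r}")
        if self.alpha_step <= 0 or self.alpha_max <= 0:
            raise InvalidInputError("alpha_step and alpha_max must be positive")
        if self.alpha0 < 0 or self.beta < 0:
            raise InvalidInputError("alpha0 and beta must be non-negative")

    @property
    def lambda_grid(self) -> np.ndarray:
        return np.geomspace(self.lambda_grid_min, self.lambda_grid_max, self.lambda_grid_size)


@dataclass
class IterationTrace:
    """Per-pass log of the Step 3 loops."""

    alphas: list[float] = field(default_factory=list)
    ne_b: list[int] = field(default_factory=list)
    ne_f: list[int] = field(default_factory=list)
    inner_pass: list[int] = field(default_factory=list)
    termination_reason: str = ""
    lambda1_hat: np.ndarray | None = None
    lambda2_hat: np.ndarray | None = None
    lambda1_ridge: np.ndarray | None = None


def _as_centered(Y, X) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    if isinstance(Y, ExpressionMatrix):
        Yc, gene_ids = Y.centered, Y.gene_ids
    else:
        Y = ExpressionMatrix(np.asarray(Y, dtype=float))
        Yc, gene_ids = Y.centered, Y.gene_ids
    if isinstance(X, GenotypeMatrix):
        Xc, snp_ids = X.centered, X.snp_ids
    else:
        X = GenotypeMatrix(np.asarray(X))
        Xc, snp_ids = X.centered, X.snp_ids
    if Yc.shape[1] != Xc.shape[1]:
        raise InvalidInputError(
            f"expression has {Yc.shape[1]} samples but genotypes have {Xc.shape[1]}"
        )
    return Yc, Xc, gene_ids, snp_ids


def refit_ridge_restricted(
    Yc: np.ndarray,
    Xc: np.ndarray,
    eqtl_map: dict[int, int],
    lambda1_vec: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene ridge on the gene block with the single retained SNP fitted
    unpenalized; genes absent from ``eqtl_map`` get an all-zero f row."""
    m_g, m_s = Yc.shape[0], Xc.shape[0]
    B = np.zeros((m_g, m_g))
    F = np.zeros((m_g, m_s))
    for i in range(m_g):
        b_sub, f_val = _restricted_ridge_gene(
            Yc, Xc, i, eqtl_map.get(i), float(lambda1_vec[i])
        )
        B[i] = np.insert(b_sub, i, 0.0)
        if i in eqtl_map:
            F[i, eqtl_map[i]] = f_val
    return B, F


def _restricted_ridge_gene(
    Yc: np.ndarray, Xc: np.ndarray, i: int, snp: int | None, lam1: float,
    Yc_test: np.ndarray | None = None, Xc_test: np.ndarray | None = None,
):
    """Solve min ||y - b Y_(-i) - f x_snp||^2 + lam1 ||b||^2 exactly."""
    y = Yc[i]
    Yt = np.delete(Yc, i, axis=0)
    p = Yt.shape[0]
    if snp is None:
        theta = np.linalg.solve(Yt @ Yt.T + lam1 * np.eye(p), Yt @ y)
        return theta, 0.0
    D = np.vstack([Yt, Xc[snp]])
    pen = np.zeros(p + 1)
    pen[:p] = lam1
    theta = np.linalg.solve(D @ D.T + np.diag(pen), D @ y)
    return theta[:p], float(theta[p])


def restricted_ridge_cv(
    Yc: np.ndarray,
    Xc: np.ndarray,
    eqtl_map: dict[int, int],
    lambda_grid: np.ndarray,
    k_folds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-gene lambda1 for the restricted ridge by K-fold held-out error."""
    m_g, n = Yc.shape
    folds = kfold_indices(n, k_folds, rng)
    err = np.zeros((m_g, lambda_grid.size))
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Ytr, Yte = Yc[:, train_idx], Yc[:, test_idx]
        Xtr, Xte = Xc[:, train_idx], Xc[:, test_idx]
        for i in range(m_g):
            snp = eqtl_map.get(i)
            Yt_te = np.delete(Yte, i, axis=0)
            for g, lam1 in enumerate(lambda_grid):
                b_sub, f_val = _restricted_ridge_gene(Ytr, Xtr, i, snp, float(lam1))
                resid = Yte[i] - b_sub @ Yt_te
                if snp is not None:
                    resid = resid - f_val * Xte[snp]
                err[i, g] += resid @ resid
    return lambda_grid[err.argmin(axis=1)]


def adaptive_lasso_cv(
    Yc: np.ndarray,
    Xc: np.ndarray,
    B_ref: np.ndarray,
    F_ref: np.ndarray,
    alpha: float,
    beta: float,
    lambda_grid: np.ndarray,
    k_folds: int,
    rng: np.random.Generator,
    cd_tol: float = 1e-6,
    cd_max_sweeps: int = 10_000,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (lambda1, lambda2) for the adaptive lasso by K-fold CV with
    the one-standard-error rule.

    Weights come from the reference estimates (the restricted-ridge refit);
    solves are warm-started down the grid within each fold. Because this CV
    sets the sparsity of the final network, the selected pair is the most
    parsimonious one (largest lambda1, then largest lambda2) whose mean
    held-out error is within one standard error of the grid minimum —
    CV-minimizing ell1 penalties systematically overselect.
    """
    from ._solvers import solve_quadratic_l1

    m_g, n = Yc.shape
    m_s = Xc.shape[0]
    folds = kfold_indices(n, k_folds, rng)
    order = np.argsort(lambda_grid)[::-1]
    err = np.zeros((m_g, k_folds, lambda_grid.size, lambda_grid.size))
    for fold, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Ytr, Yte = Yc[:, train_idx], Yc[:, test_idx]
        Xtr, Xte = Xc[:, train_idx], Xc[:, test_idx]
        for i in range(m_g):
            w = make_weights(B_ref[i], F_ref[i], alpha, beta, zero_tol)
            y = Ytr[i]
            Yt = np.delete(Ytr, i, axis=0)
            D = np.vstack([Yt, Xtr])
            G = D @ D.T
            d = D @ y
            yty = float(y @ y)
            wb = np.delete(w.w_b, i)
            Dte = np.vstack([np.delete(Yte, i, axis=0), Xte])
            for g2 in order:
                lam2 = float(lambda_grid[g2])
                theta = None
                for g1 in order:
                    lam1 = float(lambda_grid[g1])
                    thr = np.concatenate([lam1 * wb, lam2 * w.w_f])
                    sol = solve_quadratic_l1(
                        G, d, yty, thr, theta0=theta, tol=cd_tol,
                        max_sweeps=cd_max_sweeps,
                    )
                    theta = sol.theta
                    resid = Yte[i] - theta @ Dte
                    err[i, fold, g1, g2] += resid @ resid
    lam1_out = np.zeros(m_g)
    lam2_out = np.zeros(m_g)
    for i in range(m_g):
        mean = err[i].mean(axis=0)
        se = err[i].std(axis=0, ddof=1) / np.sqrt(k_folds)
        g1_min, g2_min = np.unravel_index(mean.argmin(), mean.shape)
        cutoff = mean[g1_min, g2_min] + se[g1_min, g2_min]
        ok1, ok2 = np.nonzero(mean <= cutoff)
        # most parsimonious qualifying pair: largest lambda1, then lambda2
        key = np.lexsort((lambda_grid[ok2], lambda_grid[ok1]))[-1]
        lam1_out[i] = lambda_grid[ok1[key]]
        lam2_out[i] = lambda_grid[ok2[key]]
    return lam1_out, lam2_out


def _fit_all_adaptive(
    Yc, Xc, B_ref, F_ref, alpha, beta, lam1_vec, lam2_vec,
    warm_B, warm_F, cfg: IalConfig,
) -> tuple[np.ndarray, np.ndarray]:
    m_g, m_s = Yc.shape[0], Xc.shape[0]
    B = np.zeros((m_g, m_g))
    F = np.zeros((m_g, m_s))
    for i in range(m_g):
        w = make_weights(B_ref[i], F_ref[i], alpha, beta, cfg.zero_tol)
        b, f, _ = adaptive_lasso_fit_gene(
            i, Yc, Xc, w, float(lam1_vec[i]), float(lam2_vec[i]),
            init_b=warm_B[i], init_f=warm_F[i],
            tol=cfg.cd_tol, max_sweeps=cfg.cd_max_sweeps,
        )
        B[i], F[i] = b, f
    return B, F


def _n_edges(M: np.ndarray, zero_tol: float) -> int:
    return int(np.count_nonzero(np.abs(M) > zero_tol))


def run_ial(
    Y,
    X,
    config: IalConfig | None = None,
    known_eqtls: dict[int, int] | None = None,
) -> SgrnResult:
    """Run the full inference and return the final (B, F) with diagnostics.

    Parameters
    ----------
    Y, X
        Expression (genes x samples) and genotype (snps x samples) data;
        either the package containers or raw arrays. Rows are centered
        internally.
    config
        Pipeline configuration; defaults to ``IalConfig()`` (IAL2 mode).
    known_eqtls
        Gene index -> SNP index map. Required (and must cover every gene)
        in IAL1 mode; must be omitted in IAL2 mode.
    """
    cfg = IalConfig() if config is None else config
    Yc, Xc, gene_ids, snp_ids = _as_centered(Y, X)
    m_g, m_s = Yc.shape[0], Xc.shape[0]
    # independent streams for the screening stages and for Step 3, so that
    # IAL1 and IAL2 draw identical Step 3 CV folds for the same seed (they
    # then agree exactly whenever Steps 1-2 recover the supplied eQTL map)
    rng = np.random.default_rng([cfg.seed, 12])
    rng_step3 = np.random.default_rng([cfg.seed, 3])
    grid = cfg.lambda_grid
    stage_supports: dict[str, set] = {}
    lambdas: dict[str, np.ndarray] = {}

    if cfg.mode == IAL1:
        if known_eqtls is None:
            raise InvalidInputError("IAL1 mode requires a known eQTL map")
        missing = [i for i in range(m_g) if i not in known_eqtls]
        if missing:
            raise InvalidInputError(
                f"IAL1 eQTL map must cover every gene; missing {missing[:5]}"
            )
        bad = [j for j in known_eqtls.values() if not 0 <= j < m_s]
        if bad:
            raise InvalidInputError(f"eQTL map references unknown SNP index {bad[0]}")
        eqtl_map = dict(known_eqtls)
        fallback_genes: set[int] = set()
    else:
        if known_eqtls is not None:
            raise InvalidInputError("IAL2 mode infers the eQTL map; do not supply one")
        # Step 1-1: ridge with CV-selected penalties
        lam1, lam2 = ridge_cv(Yc, Xc, grid, cfg.k_folds, rng)
        ridge = ridge_fit_all(Yc, Xc, lam1, lam2)
        lambdas["ridge_lambda1"], lambdas["ridge_lambda2"] = lam1, lam2
        stage_supports["step1_1_ridge_F"] = support(ridge.F_ridge, cfg.zero_tol)
        logger.info("step 1-1 ridge done (M_g=%d, M_s=%d)", m_g, m_s)
        # Step 1-2: elastic-net SNP screen
        F_en = np.zeros((m_g, m_s))
        lam2_en = np.zeros(m_g)
        for i in range(m_g):
            lam2_en[i] = elastic_net_cv_lambda2(
                i, Yc, Xc, float(lam1[i]), grid, cfg.k_folds, rng,
                tol=cfg.cd_tol, max_sweeps=cfg.cd_max_sweeps,
            )
            _, F_en[i], _ = elastic_net_fit_gene(
                i, Yc, Xc, float(lam1[i]), float(lam2_en[i]),
                tol=cfg.cd_tol, max_sweeps=cfg.cd_max_sweeps,
            )
        lambdas["elastic_net_lambda2"] = lam2_en
        cand = truncate_candidates(F_en, cfg.n_k, cfg.zero_tol)
        stage_supports["step1_2_elastic_net_F"] = support(cand.F_cand, cfg.zero_tol)
        logger.info(
            "step 1-2 elastic net done: %d candidate eQTL slots",
            len(stage_supports["step1_2_elastic_net_F"]),
        )
        # Step 2: lasso-path single-eQTL finalization
        assignment = assign_eqtls(
            Yc, Xc, cand, n_path=cfg.n_path, path_min_ratio=cfg.path_min_ratio,
            tol=cfg.cd_tol, max_sweeps=cfg.cd_max_sweeps, zero_tol=cfg.zero_tol,
        )
        eqtl_map = assignment.snp_of_gene
        fallback_genes = assignment.fallback_genes
        stage_supports["step2_eqtl_F"] = {(i, j) for i, j in eqtl_map.items()}
        logger.info(
            "step 2 lasso path done: %d genes assigned, %d fallbacks",
            len(eqtl_map), len(fallback_genes),
        )

    # ------------------------------------------------------------------
    # Step 3: iterative adaptive lasso (Algorithm 3)
    trace = IterationTrace()
    lam1R = restricted_ridge_cv(Yc, Xc, eqtl_map, grid, cfg.k_folds, rng_step3)
    B_R, F_R = refit_ridge_restricted(Yc, Xc, eqtl_map, lam1R)
    lambdas["restricted_ridge_lambda1"] = lam1R
    trace.lambda1_ridge = lam1R

    lam1_hat, lam2_hat = adaptive_lasso_cv(
        Yc, Xc, B_R, F_R, cfg.alpha0, cfg.beta, grid, cfg.k_folds, rng_step3,
        cd_tol=cfg.cd_tol, cd_max_sweeps=cfg.cd_max_sweeps, zero_tol=cfg.zero_tol,
    )
    lambdas["adaptive_lambda1"], lambdas["adaptive_lambda2"] = lam1_hat, lam2_hat
    trace.lambda1_hat, trace.lambda2_hat = lam1_hat, lam2_hat

    # The ridge refit seeds both the warm start and the first pass's
    # weights, so the first inner loop at alpha0 always registers the
    # dense-to-sparse collapse as a change and the alpha sweep proceeds.
    alpha = cfg.alpha0
    B, F = B_R, F_R
    while True:
        changed = False
        for inner in range(1, cfg.max_inner + 1):
            ne_before = _n_edges(B, cfg.zero_tol)
            B_new, F_new = _fit_all_adaptive(
                Yc, Xc, B, F, alpha, cfg.beta, lam1_hat, lam2_hat, B, F, cfg
            )
            B, F = B_new, F_new
            ne_after = _n_edges(B, cfg.zero_tol)
            trace.alphas.append(alpha)
            trace.ne_b.append(ne_after)
            trace.ne_f.append(_n_edges(F, cfg.zero_tol))
            trace.inner_pass.append(inner)
            logger.info("step 3: alpha=%.2f inner=%d N_e(B)=%d N_e(F)=%d",
                        alpha, inner, ne_after, trace.ne_f[-1])
            if ne_after == ne_before:
                break
            changed = True
        if not changed:
            trace.termination_reason = "no change in N_e(B)"
            break
        alpha = round(alpha + cfg.alpha_step, 10)
        if alpha > cfg.alpha_max + 1e-12:
            trace.termination_reason = "alpha_max reached"
            break

    stage_supports["step3_B"] = support(B, cfg.zero_tol)
    stage_supports["step3_F"] = support(F, cfg.zero_tol)
    F_final = EqtlMatrix(np.where(np.abs(F) > cfg.zero_tol, F, 0.0))
    B_final = GeneAdjacency(np.where(np.abs(B) > cfg.zero_tol, B, 0.0))
    return SgrnResult(
        B_final=B_final,
        F_final=F_final,
        eqtl_map=F_final.assignment(cfg.zero_tol),
        stage_supports=stage_supports,
        lambdas=lambdas,
        trace=trace,
        gene_ids=gene_ids,
        snp_ids=snp_ids,
        fallback_genes=fallback_genes,
    )


def config_with(config: IalConfig | None = None, **overrides) -> IalConfig:
    """Convenience: a copy of ``config`` (or the defaults) with fields replaced."""
    return replace(IalConfig() if config is None else config, **overrides)
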