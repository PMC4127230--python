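"""Structure-recovery metrics and the simulation benchmark harness.

Recovery of a network support is scored by comparing true and inferred edge
sets over a fixed universe of assessable slots:

    TPR = TP / (TP + FN),    FDR = FP / (TP + FP)

with FDR defined as 0 when nothing is predicted. For the gene-gene matrix B
the universe is all directed off-diagonal slots ((i, j) and (j, i) are
distinct); an inferred edge counts as positive whenever its coefficient
exceeds the zero tolerance, regardless of sign or magnitude. eQTL
assignments are scored per gene: a correct SNP is one TP, a wrong SNP one
FP plus one FN, a missing assignment one FN.

``run_benchmark`` ties the generator, the inference pipeline, and the
metrics together: for each (M, N, E_g) setting, mode, and replicate it
simulates a fresh random network (replicate seeds are base_seed +
replicate index), runs inference, and emits one tidy row per run plus a
per-cell summary of means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DEFAULT_ZERO_TOL, InvalidInputError
from .pipeline import IAL1, IAL2, IalConfig, config_with, run_ial
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

Edge = tuple[int, int]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def structure_metrics(
    true_support: set[Edge],
    inferred_support: set[Edge],
    universe: set[Edge],
) -> tuple[float, float, ConfusionCounts]:
    """TPR, FDR and the full confusion counts over ``universe``."""
    true_support = set(true_support)
    inferred_support = set(inferred_support)
    if not true_support <= universe or not inferred_support <= universe:
        raise InvalidInputError("supports must lie inside the slot universe")
    tp = len(true_support & inferred_support)
    fp = len(inferred_support - true_support)
    fn = len(true_support - inferred_support)
    tn = len(universe) - tp - fp - fn
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    return tpr, fdr, ConfusionCounts(tp, fp, tn, fn)


def b_universe(n_genes: int) -> set[Edge]:
    """All directed off-diagonal gene-gene slots."""
    return {(i, j) for i in range(n_genes) for j in range(n_genes) if i != j}


def eqtl_assignment_metrics(
    true_map: dict[int, int],
    inferred_map: dict[int, int],
    n_genes: int,
) -> tuple[float, float, ConfusionCounts]:
    """Score per-gene single-eQTL assignments.

    Each gene contributes one prediction slot: matching SNP -> TP; wrong
    SNP -> FP + FN; missing prediction for a gene with a true eQTL -> FN;
    prediction for a gene without one -> FP.
    """
    tp = fp = fn = 0
    for i in range(n_genes):
        truth = true_map.get(i)
        pred = inferred_map.get(i)
        if truth is not None and pred is not None:
            if truth == pred:
                tp += 1
            else:
                fp += 1
                fn += 1
        elif truth is not None:
            fn += 1
        elif pred is not None:
            fp += 1
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    tn = 0
    return tpr, fdr, ConfusionCounts(tp, fp, tn, fn)


def score_result(dataset, result, zero_tol: float = DEFAULT_ZERO_TOL) -> dict[str, float]:
    """TPR/FDR of B recovery and of the eQTL assignment for one run."""
    m = dataset.model.n_genes
    tpr_b, fdr_b, _ = structure_metrics(
        dataset.model.B.support(zero_tol), result.B_final.support(zero_tol), b_universe(m)
    )
    true_map = dataset.model.F.assignment(zero_tol)
    tpr_f, fdr_f, _ = eqtl_assignment_metrics(true_map, result.eqtl_map, m)
    return {"tpr_b": tpr_b, "fdr_b": fdr_b, "tpr_eqtl": tpr_f, "fdr_eqtl": fdr_f}


def run_benchmark(
    settings: list[tuple[int, int, float]],
    modes: list[str],
    replicates: int,
    base_seed: int,
    ial_config: IalConfig | None = None,
    sim_overrides: dict | None = None,
) -> pd.DataFrame:
    """Simulate-infer-score over a grid of (M, N, E_g) settings.

    Returns a tidy frame with one row per setting x mode x replicate. A
    replicate that fails is recorded with NaN metrics and the error message
    rather than aborting the run.
    """
    if replicates < 1:
        raise InvalidInputError("need at least one replicate")
    for mode in modes:
        if mode not in (IAL1, IAL2):
            raise InvalidInputError(f"unknown mode {mode!r}")
    rows = []
    for (m, n, e_g) in settings:
        for rep in range(replicates):
            seed = base_seed + rep
            sim_cfg = SimulationConfig(
                n_genes=m, n_samples=n, edges_per_gene=e_g, seed=seed,
                **(sim_overrides or {}),
            )
            dataset = simulate_dataset(sim_cfg)
            true_map = dataset.model.F.assignment()
            for mode in modes:
                row = {
                    "M": m, "N": n, "E_g": e_g, "mode": mode,
                    "replicate": rep, "seed": seed, "error": "",
                }
                try:
                    cfg = config_with(ial_config, mode=mode, seed=seed)
                    known = true_map if mode == IAL1 else None
                    result = run_ial(dataset.Y, dataset.X, cfg, known_eqtls=known)
                    row.update(score_result(dataset, result))
                except Exception as err:  # noqa: BLE001 - recorded, not fatal
                    logger.warning("replicate failed (%s, M=%d, N=%d): %s", mode, m, n, err)
                    row.update({k: np.nan for k in ("tpr_b", "fdr_b", "tpr_eqtl", "fdr_eqtl")})
                    row["error"] = str(err)
                rows.append(row)
                logger.info(
                    "benchmark %s M=%d N=%d E_g=%g rep=%d: TPR=%.4f FDR=%.4f",
                    mode, m, n, e_g, rep,
                    row.get("tpr_b", float("nan")), row.get("fdr_b", float("nan")),
                )
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell means in the layout of the reference accuracy table
    (rows N x M, one TPR and FDR column pair per mode)."""
    summary = (
        table.groupby(["N", "M", "E_g", "mode"])[["tpr_b", "fdr_b", "tpr_eqtl", "fdr_eqtl"]]
        .mean()
        .reset_index()
    )
    wide = summary.pivot_table(
        index=["N", "M", "E_g"], columns="mode",
        values=["tpr_b", "fdr_b"],
    )
    wide.columns = [f"{metric}_{mode}" for metric, mode in wide.columns]
    return wide.reset_index()


def plot_benchmark(table: pd.DataFrame, out_path: str) -> None:
    """TPR and FDR versus sample size, one panel pair per (M, E_g)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = sorted(table.groupby(["M", "E_g"]).groups)
    fig, axes = plt.subplots(len(cells), 2, figsize=(9, 3 * len(cells)), squeeze=False)
    for row_idx, (m, e_g) in enumerate(cells):
        sub = table[(table["M"] == m) & (table["E_g"] == e_g)]
        for col_idx, metric in enumerate(("tpr_b", "fdr_b")):
            ax = axes[row_idx][col_idx]
            for mode, grp in sub.groupby("mode"):
                means = grp.groupby("N")[metric].mean()
                ax.plot(means.index, means.values, marker="o", label=mode)
            ax.set_xlabel("samples (N)")
            ax.set_ylabel(metric.replace("_b", " (B)").upper())
            ax.set_title(f"M={m}, E_g={e_g:g}")
            ax.set_ylim(-0.02, 1.02)
            ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
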