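"""Synthetic SEM benchmark generator.

Generates random directed acyclic gene networks and matched expression /
genotype datasets with known ground truth:

* a uniform random permutation of the genes fixes a topological order;
  directed edges are sampled only from later to earlier positions, so the
  adjacency is strictly triangular under that order (acyclic by
  construction);
* each admissible edge slot is included independently with probability
  chosen so the expected edge count is ``edges_per_gene * n_genes``;
* nonzero coefficients (both gene-gene and eQTL effects) are drawn
  uniformly from [0.5, 1] in magnitude with a random sign;
* one SNP per gene: ``F`` is diagonal with a full diagonal (SNP i is the
  true eQTL of gene i), so the SNP panel has the same size as the gene set;
* genotypes are i.i.d. over {1, 2, 3} with probabilities (0.25, 0.5, 0.25),
  i.e. Hardy-Weinberg at minor-allele frequency one half;
* expression solves the structural model: Y = (I - B)^-1 (F X + E) with
  E_ij ~ Normal(0, noise_variance), default variance 0.01.

The noise realization ``E`` is stored with the dataset so that the SEM
residual (I - B) Y - F X can be checked to recover it exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datatypes import (
    EqtlMatrix,
    ExpressionMatrix,
    GeneAdjacency,
    GenotypeMatrix,
    InvalidInputError,
    SemModel,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic benchmark.

    Defaults are the benchmark's study conditions: coefficients uniform on
    +/-[0.5, 1], Gaussian noise with variance 0.01, genotype frequencies
    (0.25, 0.5, 0.25), and a single eQTL per gene.
    """

    n_genes: int = 10
    n_samples: int = 100
    edges_per_gene: float = 1.0
    eqtls_per_gene: int = 1
    coef_low: float = 0.5
    coef_high: float = 1.0
    noise_variance: float = 0.01
    genotype_probs: tuple[float, float, float] = (0.25, 0.5, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_samples < 2:
            raise InvalidInputError("need at least 2 genes and 2 samples")
        if self.eqtls_per_gene != 1:
            raise InvalidInputError("only a single eQTL per gene is supported")
        if not self.coef_low < self.coef_high:
            raise InvalidInputError("coef_low must be < coef_high")
        if abs(sum(self.genotype_probs) - 1.0) > 1e-12:
            raise InvalidInputError("genotype_probs must sum to 1")
        max_edges = self.n_genes * (self.n_genes - 1) / 2
        if self.edges_per_gene * self.n_genes > max_edges:
            raise InvalidInputError(
                f"edge budget {self.edges_per_gene * self.n_genes:.1f} exceeds the "
                f"{max_edges:.0f} acyclic slots of a {self.n_genes}-gene network"
            )


@dataclass
class SimulatedDataset:
    """A ground-truth model together with one generated (Y, X) realization."""

    model: SemModel
    Y: ExpressionMatrix
    X: GenotypeMatrix
    noise: np.ndarray
    config: SimulationConfig
    topological_order: np.ndarray


def _draw_coefficients(rng: np.random.Generator, size: int, low: float, high: float) -> np.ndarray:
    mag = rng.uniform(low, high, size=size)
    sign = rng.choice([-1.0, 1.0], size=size)
    return mag * sign


def sample_network(config: SimulationConfig, rng: np.random.Generator) -> tuple[SemModel, np.ndarray]:
    """Draw a random acyclic SEM (B, F).

    Returns the model and the topological order used (a permutation ``p``
    such that ``B[p][:, p]`` is strictly lower triangular: edges point from
    later positions in ``p`` to earlier ones... i.e. row index above column
    index after permutation).
    """
    m = config.n_genes
    order = rng.permutation(m)  # order[k] = gene placed at topological rank k
    # admissible slots: target at rank r regulated by source at rank s < r
    n_slots = m * (m - 1) // 2
    p_edge = config.edges_per_gene * m / n_slots
    B = np.zeros((m, m))
    ranks_i, ranks_j = np.tril_indices(m, k=-1)
    include = rng.random(n_slots) < p_edge
    n_edges = int(include.sum())
    coefs = _draw_coefficients(rng, n_edges, config.coef_low, config.coef_high)
    tgt = order[ranks_i[include]]
    src = order[ranks_j[include]]
    B[tgt, src] = coefs
    F = np.zeros((m, m))
    np.fill_diagonal(F, _draw_coefficients(rng, m, config.coef_low, config.coef_high))
    model = SemModel(
        B=GeneAdjacency(B), F=EqtlMatrix(F), noise_variance=config.noise_variance
    )
    return model, order


def sample_genotypes(config: SimulationConfig, rng: np.random.Generator) -> GenotypeMatrix:
    """Draw i.i.d. genotypes over {1, 2, 3} with the configured frequencies."""
    vals = rng.choice(
        [1, 2, 3],
        size=(config.n_genes, config.n_samples),
        p=np.asarray(config.genotype_probs),
    )
    return GenotypeMatrix(vals)


def generate_expression(
    model: SemModel, X: GenotypeMatrix, rng: np.random.Generator,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Solve the structural model for expression: Y = (I - B)^-1 (F X + E).

    Returns the expression matrix and the noise realization ``E``.
    """
    m = model.n_genes
    i_minus_b = np.eye(m) - model.B.values
    sd = float(np.sqrt(model.noise_variance))
    E = rng.normal(0.0, sd, size=(m, X.n_samples)) if sd > 0 else np.zeros((m, X.n_samples))
    try:
        Y = np.linalg.solve(i_minus_b, model.F.values @ X.values + E)
    except np.linalg.LinAlgError as err:  # pragma: no cover - guarded in SemModel
        raise InvalidInputError("(I - B) is singular; cannot generate expression") from err
    return ExpressionMatrix(Y), E


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete benchmark dataset from the configured seed."""
    rng = np.random.default_rng(config.seed)
    model, order = sample_network(config, rng)
    X = sample_genotypes(config, rng)
    Y, E = generate_expression(model, X, rng)
    return SimulatedDataset(
        model=model, Y=Y, X=X, noise=E, config=config, topological_order=order
    )


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset as TSV + JSON provenance under ``out_dir``.

    Emits expression.tsv, genotypes.tsv (genes/snps x samples with a header
    row of sample ids), true_edges.tsv (regulator_gene, target_gene,
    weight), true_eqtls.tsv (gene, snp, weight), and simulation.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write_matrix(path: Path, row_ids, sample_ids, values, fmt) -> None:
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("id\t" + "\t".join(sample_ids) + "\n")
            for rid, row in zip(row_ids, values):
                fh.write(rid + "\t" + "\t".join(fmt(v) for v in row) + "\n")

    paths["expression"] = out / "expression.tsv"
    _write_matrix(
        paths["expression"], dataset.Y.gene_ids, dataset.Y.sample_ids,
        dataset.Y.values, lambda v: f"{v:.10g}",
    )
    paths["genotypes"] = out / "genotypes.tsv"
    _write_matrix(
        paths["genotypes"], dataset.X.snp_ids, dataset.X.sample_ids,
        dataset.X.values, lambda v: str(int(v)),
    )

    paths["true_edges"] = out / "true_edges.tsv"
    with paths["true_edges"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("regulator_gene\ttarget_gene\tweight\n")
        for (i, j) in sorted(dataset.model.B.support()):
            fh.write(
                f"{dataset.Y.gene_ids[j]}\t{dataset.Y.gene_ids[i]}\t"
                f"{dataset.model.B.values[i, j]:.10g}\n"
            )
    paths["true_eqtls"] = out / "true_eqtls.tsv"
    with paths["true_eqtls"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tsnp\tweight\n")
        for (i, j) in sorted(dataset.model.F.support()):
            fh.write(
                f"{dataset.Y.gene_ids[i]}\t{dataset.X.snp_ids[j]}\t"
                f"{dataset.model.F.values[i, j]:.10g}\n"
            )

    paths["provenance"] = out / "simulation.json"
    cfg = dataclasses.asdict(dataset.config)
    cfg["genotype_probs"] = list(cfg["genotype_probs"])
    paths["provenance"].write_text(json.dumps(cfg, indent=2) + "\n", encoding="utf-8")
    return paths
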