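"""Core data containers for SNP-gene regulatory network (SGRN) inference.

The structural equation model (SEM) underlying the whole package relates the
expression of each gene to the expression of every other gene and to the
genotypes of a panel of SNPs:

    y_i = b_i Y + f_i X + mu_i + eps_i

where ``Y`` is the (genes x samples) expression matrix, ``X`` the
(snps x samples) genotype matrix, ``b_i`` the i-th row of the gene-gene
adjacency ``B`` (zero diagonal: no self-regulation), ``f_i`` the i-th row of
the gene-SNP effect matrix ``F``, and ``eps_i`` zero-mean Gaussian noise.
Row-centering both ``Y`` and ``X`` eliminates the per-gene bias ``mu_i``, so
every regression in the package consumes centered data.

Conventions:

* row-vector orientation throughout — coefficient rows left-multiply data
  matrices, i.e. predictions are ``b_i @ Y + f_i @ X``;
* genotypes are stored raw with the {1, 2, 3} coding (minor-allele count
  plus one) and centered lazily;
* gene/SNP indices are 0-based internally; file I/O is by identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Magnitude below which a coefficient is treated as a structural zero when
#: extracting edge supports.
DEFAULT_ZERO_TOL = 1e-8

GENOTYPE_CODES = (1, 2, 3)


class InvalidInputError(ValueError):
    """Raised when user-supplied data violates a structural contract."""


def center_rows(matrix: np.ndarray) -> np.ndarray:
    """Return a copy of ``matrix`` with every row shifted to zero mean.

    Parameters
    ----------
    matrix
        Two-dimensional real array with at least one column.

    Returns
    -------
    numpy.ndarray
        New float array of the same shape; the input is not modified.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidInputError(
            f"expected a non-empty 2-D matrix, got shape {arr.shape}"
        )
    return arr - arr.mean(axis=1, keepdims=True)


def support(matrix: np.ndarray, zero_tol: float = DEFAULT_ZERO_TOL) -> set[tuple[int, int]]:
    """Index pairs ``(i, j)`` where ``|m_ij| > zero_tol``."""
    if zero_tol < 0:
        raise InvalidInputError("zero_tol must be non-negative")
    arr = np.asarray(matrix, dtype=float)
    rows, cols = np.nonzero(np.abs(arr) > zero_tol)
    return {(int(i), int(j)) for i, j in zip(rows, cols)}


def _as_ids(prefix: str, n: int, ids: Sequence[str] | None) -> list[str]:
    if ids is None:
        return [f"{prefix}{k}" for k in range(n)]
    ids = [str(s) for s in ids]
    if len(ids) != n:
        raise InvalidInputError(f"expected {n} identifiers, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise InvalidInputError("identifiers must be unique")
    return ids


@dataclass
class ExpressionMatrix:
    """Gene expression levels, genes x samples.

    ``values`` holds the data as given; ``centered`` returns the row-centered
    copy that every regression consumes.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default=None)  # type: ignore[assignment]
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("expression matrix must be 2-D")
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise InvalidInputError(
                f"need at least 2 genes and 2 samples, got shape {(m, n)}"
            )
        self.gene_ids = _as_ids("gene", m, self.gene_ids)
        self.sample_ids = _as_ids("sample", n, self.sample_ids)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def centered(self) -> np.ndarray:
        return center_rows(self.values)


@dataclass
class GenotypeMatrix:
    """SNP genotypes, snps x samples, coded {1, 2, 3} = minor-allele count + 1."""

    values: np.ndarray
    snp_ids: list[str] = field(default=None)  # type: ignore[assignment]
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise InvalidInputError("genotype matrix must be 2-D")
        if not np.isin(arr, GENOTYPE_CODES).all():
            bad = arr[~np.isin(arr, GENOTYPE_CODES)]
            raise InvalidInputError(
                f"genotype entries must be coded 1/2/3 (minor-allele count + 1); "
                f"found {bad.flat[0]!r}"
            )
        self.values = arr.astype(np.int64)
        m, n = self.values.shape
        self.snp_ids = _as_ids("snp", m, self.snp_ids)
        self.sample_ids = _as_ids("sample", n, self.sample_ids)

    @property
    def n_snps(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def centered(self) -> np.ndarray:
        return center_rows(self.values)


@dataclass
class GeneAdjacency:
    """Directed gene-gene effect matrix ``B``; ``b_ij != 0`` means gene j
    regulates gene i. The diagonal is identically zero (no self-loops)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m, m2 = self.values.shape
        if m != m2:
            raise InvalidInputError("gene adjacency must be square")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 0:
            raise InvalidInputError("gene adjacency diagonal must be zero (no self-loops)")

    def support(self, zero_tol: float = DEFAULT_ZERO_TOL) -> set[tuple[int, int]]:
        return support(self.values, zero_tol)

    @property
    def n_edges(self) -> int:
        """N_e(B): number of selected gene-gene edges."""
        return len(self.support())


@dataclass
class EqtlMatrix:
    """Gene-SNP effect matrix ``F``; ``f_ij != 0`` means SNP j is an eQTL of
    gene i. Final pipeline output carries at most one nonzero per row."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("eQTL matrix must be 2-D")

    def support(self, zero_tol: float = DEFAULT_ZERO_TOL) -> set[tuple[int, int]]:
        return support(self.values, zero_tol)

    @property
    def n_edges(self) -> int:
        return len(self.support())

    def assignment(self, zero_tol: float = DEFAULT_ZERO_TOL) -> dict[int, int]:
        """Per-gene eQTL assignment, gene index -> SNP index.

        Requires at most one above-tolerance entry per row; genes with an
        all-zero row are absent from the map.
        """
        out: dict[int, int] = {}
        for i, row in enumerate(self.values):
            nz = np.flatnonzero(np.abs(row) > zero_tol)
            if len(nz) > 1:
                raise InvalidInputError(
                    f"gene {i} has {len(nz)} eQTLs; final output allows at most one"
                )
            if len(nz) == 1:
                out[i] = int(nz[0])
        return out


@dataclass
class SemModel:
    """A fully specified structural equation model (B, F, noise variance)."""

    B: GeneAdjacency
    F: EqtlMatrix
    noise_variance: float = 0.01

    def __post_init__(self) -> None:
        if self.noise_variance < 0:
            raise InvalidInputError("noise variance must be non-negative")
        m = self.B.values.shape[0]
        if self.F.values.shape[0] != m:
            raise InvalidInputError("B and F must agree on the number of genes")
        # (I - B) must be invertible for the generating equation to be solvable
        i_minus_b = np.eye(m) - self.B.values
        if abs(np.linalg.det(i_minus_b)) < 1e-12:
            raise InvalidInputError("(I - B) is singular; model cannot generate data")

    @property
    def n_genes(self) -> int:
        return self.B.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.F.values.shape[1]


@dataclass
class SgrnResult:
    """Full output of an inference run: final (B, F), the per-gene eQTL map,
    the supports surviving each stage, regularization choices, and loop
    diagnostics (attached by the pipeline)."""

    B_final: GeneAdjacency
    F_final: EqtlMatrix
    eqtl_map: dict[int, int]
    stage_supports: dict[str, set[tuple[int, int]]]
    lambdas: dict[str, np.ndarray]
    trace: object = None  # IterationTrace; typed loosely to avoid a cycle
    gene_ids: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)
    #: genes whose eQTL came from the screening fallback rather than a
    #: genuine first entry on the lasso path
    fallback_genes: set[int] = field(default_factory=set)
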