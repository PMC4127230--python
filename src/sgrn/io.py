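"""File formats: TSV expression/genotype tables, network exports,
optional VCF genotype import, and YAML/JSON run configuration.

Native tabular dialect is TSV (UTF-8, LF): a header row of sample ids, a
first column of feature ids. Genotypes must use the {1, 2, 3} coding
(minor-allele count + 1); a VCF can be imported instead, in which case
diploid ALT dosages 0/1/2 are shifted to 1/2/3.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GenotypeMatrix,
    InvalidInputError,
    SgrnResult,
)
from .pipeline import IalConfig


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise InvalidInputError(f"{path}: no sample columns found")
    return df


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples expression TSV."""
    df = _read_table(path)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as err:
        bad = df.apply(pd.to_numeric, errors="coerce")
        r, c = np.argwhere(bad.isna().to_numpy())[0]
        raise InvalidInputError(
            f"{path}: non-numeric expression value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        ) from err
    return ExpressionMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a snps x samples genotype TSV coded {1, 2, 3}."""
    df = _read_table(path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise InvalidInputError(
            f"{path}: non-numeric genotype at SNP {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    vals = numeric.to_numpy()
    bad = ~np.isin(vals, (1, 2, 3))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise InvalidInputError(
            f"{path}: genotype {vals[r, c]!r} at SNP {df.index[r]!r}, sample "
            f"{df.columns[c]!r} is outside the {{1,2,3}} coding "
            "(minor-allele count + 1)"
        )
    return GenotypeMatrix(
        vals.astype(np.int64), list(df.index.astype(str)), list(df.columns.astype(str))
    )


def align_samples(
    Y: ExpressionMatrix, X: GenotypeMatrix
) -> tuple[ExpressionMatrix, GenotypeMatrix]:
    """Restrict both matrices to their shared samples, in expression-file order."""
    shared = [s for s in Y.sample_ids if s in set(X.sample_ids)]
    if len(shared) < 2:
        raise InvalidInputError(
            f"expression and genotype files share only {len(shared)} sample(s); need >= 2"
        )
    if shared == Y.sample_ids == X.sample_ids:
        return Y, X
    y_idx = [Y.sample_ids.index(s) for s in shared]
    x_idx = [X.sample_ids.index(s) for s in shared]
    return (
        ExpressionMatrix(Y.values[:, y_idx], Y.gene_ids, shared),
        GenotypeMatrix(X.values[:, x_idx], X.snp_ids, shared),
    )


def read_vcf_genotypes(path: str | Path) -> GenotypeMatrix:
    """Import genotypes from a VCF: diploid ALT dosage 0/1/2 -> {1, 2, 3}.

    Requires cyvcf2. Missing or non-diploid genotypes are rejected (no
    imputation is attempted).
    """
    try:
        from cyvcf2 import VCF
    except ImportError as err:  # pragma: no cover - depends on extras
        raise InvalidInputError("VCF import requires the cyvcf2 package") from err
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, rows = [], []
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        dosages = []
        for gt in variant.genotypes:
            alleles = gt[:-1]
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                raise InvalidInputError(
                    f"{path}: variant {vid} has a missing or non-diploid genotype"
                )
            dosages.append(sum(1 for a in alleles if a > 0))
        snp_ids.append(vid)
        rows.append([d + 1 for d in dosages])
    if not rows:
        raise InvalidInputError(f"{path}: VCF contains no variants")
    return GenotypeMatrix(np.asarray(rows, dtype=np.int64), snp_ids, samples)


def read_eqtl_map(path: str | Path, gene_ids: list[str], snp_ids: list[str]) -> dict[int, int]:
    """Read a gene->SNP map TSV with columns gene, snp (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "snp" not in cols:
        raise InvalidInputError(f"{path}: eQTL map needs 'gene' and 'snp' columns")
    g_index = {g: i for i, g in enumerate(gene_ids)}
    s_index = {s: j for j, s in enumerate(snp_ids)}
    out: dict[int, int] = {}
    for _, rec in df.iterrows():
        g, s = rec[cols["gene"]], rec[cols["snp"]]
        if g not in g_index:
            raise InvalidInputError(f"{path}: unknown gene id {g!r}")
        if s not in s_index:
            raise InvalidInputError(f"{path}: unknown SNP id {s!r}")
        out[g_index[g]] = s_index[s]
    return out


# ---------------------------------------------------------------------------
# Network export


def _edge_records(result: SgrnResult):
    """Deterministic edge rows: targets ascending, then sources; gene edges
    before eQTL edges for equal (target, source) ordering stability."""
    genes, snps = result.gene_ids, result.snp_ids
    records = []
    for (i, j) in result.B_final.support():
        records.append((i, 0, genes[j], genes[i], result.B_final.values[i, j], "gene"))
    for (i, j) in result.F_final.support():
        records.append((i, 1, snps[j], genes[i], result.F_final.values[i, j], "snp"))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    return [r[2:] for r in records]


def write_network(result: SgrnResult, path: str | Path, format: str = "edgelist") -> Path:
    """Write the inferred network as an edge-list TSV or a SIF file."""
    path = Path(path)
    records = _edge_records(result)
    if format == "edgelist":
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("source\ttarget\tweight\tsource_kind\n")
            for src, tgt, w, kind in records:
                fh.write(f"{src}\t{tgt}\t{w:.10g}\t{kind}\n")
    elif format == "sif":
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            for src, tgt, _, kind in records:
                relation = "regulates" if kind == "gene" else "eqtl_of"
                fh.write(f"{src}\t{relation}\t{tgt}\n")
    else:
        raise InvalidInputError(f"unknown network format {format!r} (edgelist or sif)")
    return path


def read_edgelist(path: str | Path) -> pd.DataFrame:
    """Read back an edge-list TSV written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    needed = {"source", "target", "weight", "source_kind"}
    if not needed <= set(df.columns):
        raise InvalidInputError(f"{path}: not an edge-list file (columns {list(df.columns)})")
    return df


# ---------------------------------------------------------------------------
# Configuration and provenance


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    import yaml

    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise InvalidInputError(f"{path}: configuration must be a mapping")
    return data


def ial_config_from_mapping(data: dict) -> IalConfig:
    known = {f.name for f in dataclasses.fields(IalConfig)}
    unknown = set(data) - known
    if unknown:
        raise InvalidInputError(f"unknown configuration keys: {sorted(unknown)}")
    return IalConfig(**data)


def write_provenance(out_dir: str | Path, config: dict, seed: int) -> Path:
    """Machine-readable record of the run: config, seed, package version."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "provenance.json"
    payload = {"config": config, "seed": seed, "sgrn_version": __version__}
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n", encoding="utf-8")
    return path
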