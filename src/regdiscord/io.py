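"""Readers and writers for the standard formats the pipeline touches.

Supported formats: 10x-style MatrixMarket triples (matrix.mtx +
features.tsv + barcodes.tsv, gzip-transparent), GMT gene sets, TSV
annotation/report tables, and a flat key=value / YAML config file mirroring
:class:`~regdiscord.datatypes.PipelineConfig` field names.
"""

from __future__ import annotations

import gzip
import logging
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .datatypes import (
    CountMatrix,
    FormatError,
    PipelineConfig,
    Regulon,
    ValidationError,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_counts_mtx",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "write_counts_mtx",
    "write_report_tables",
    "read_config",
]


def _open_text(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_counts_mtx(matrix_path, features_path, barcodes_path) -> CountMatrix:
    """Load a 10x-style triple into a :class:`CountMatrix`.

    Gene order follows the features file, cell order the barcodes file.
    The features file may have one column (symbol only) or two or more
    (gene_id TAB symbol, 10x v2 dialect).
    """
    for p in (matrix_path, features_path, barcodes_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    with _open_text(matrix_path) as fh:
        header = fh.readline()
        if "matrixmarket" not in header.lower():
            raise FormatError(f"{matrix_path}: missing MatrixMarket header")
    with _open_text(matrix_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csc_matrix(mat)

    feats = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    if feats.shape[1] == 1:
        gene_ids = feats[0].to_numpy()
        symbols = feats[0].to_numpy()
    else:
        gene_ids = feats[0].to_numpy()
        symbols = feats[1].to_numpy()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)[0].to_numpy()

    if mat.shape[0] != len(gene_ids):
        raise FormatError(
            f"{features_path}: {len(gene_ids)} features but matrix has "
            f"{mat.shape[0]} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix has "
            f"{mat.shape[1]} columns"
        )
    if pd.Index(barcodes).duplicated().any():
        raise ValidationError(f"{barcodes_path}: duplicate barcode")
    return CountMatrix(values=mat, gene_ids=gene_ids, gene_symbols=symbols, cell_ids=barcodes)


def write_counts_mtx(counts: CountMatrix, out_dir) -> dict:
    """Write a CountMatrix as an uncompressed 10x-style triple."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
    }
    coo = counts.values.tocoo()
    order = np.lexsort((coo.row, coo.col))  # canonical order for byte-stable output
    with open(paths["matrix"], "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{counts.n_genes} {counts.n_cells} {coo.nnz}\n")
        for i in order:
            fh.write(f"{coo.row[i] + 1} {coo.col[i] + 1} {int(coo.data[i])}\n")
    pd.DataFrame({0: counts.gene_ids, 1: counts.gene_symbols}).to_csv(
        paths["features"], sep="\t", header=False, index=False
    )
    pd.DataFrame({0: counts.cell_ids}).to_csv(
        paths["barcodes"], sep="\t", header=False, index=False
    )
    return {k: str(v) for k, v in paths.items()}


def read_gene_sets_gmt(path) -> list[Regulon]:
    """Parse a GMT file into regulons: ``name TAB description TAB gene...``.

    The set name is taken as the head TF symbol (an optional suffix after
    the first whitespace or ``_regulon`` suffix is stripped).  Duplicate
    genes within a line are de-duplicated with a warning.
    """
    regulons = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            name = parts[0].split()[0]
            if name.endswith("_regulon"):
                name = name[: -len("_regulon")]
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise ValidationError(f"{path}:{lineno}: empty gene list")
            if len(set(genes)) != len(genes):
                log.warning("%s:%d: duplicate genes in set %s, de-duplicated", path, lineno, name)
            regulons.append(Regulon(head_tf=name, targets=frozenset(genes)))
    return regulons


def write_gene_sets_gmt(regulons: Sequence[Regulon], path) -> str:
    with open(path, "w") as fh:
        for r in sorted(regulons, key=lambda r: r.head_tf):
            genes = "\t".join(sorted(r.targets))
            fh.write(f"{r.head_tf}\tregulon\t{genes}\n")
    return str(path)


_FLOAT_FMT = "%.6g"


def _write_tsv(df: pd.DataFrame, path, sort_cols) -> None:
    if len(df) and sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_report_tables(results: dict, out_dir) -> dict:
    """Write the pipeline's report tables as TSV with deterministic row order.

    ``results`` may contain any of the keys ``de`` (per-gene hurdle results),
    ``regulon_differential``, ``interactor_calls``, ``common_targets``; each
    maps to a DataFrame.  Rows are sorted by FDR then identifier where an FDR
    column exists, else by the first identifier column.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sort_keys = {
        "de": ["fdr", "gene_id"],
        "regulon_differential": ["fdr", "regulon"],
        "interactor_calls": ["tf"],
        "common_targets": ["partner_tf", "gene"],
    }
    paths = {}
    for name, df in results.items():
        path = out / f"{name}.tsv"
        keys = [c for c in sort_keys.get(name, []) if c in df.columns]
        _write_tsv(df, path, keys)
        paths[name] = str(path)
    return paths


def read_config(path) -> PipelineConfig:
    """Load a config file: YAML mapping or flat ``key=value`` lines."""
    text = Path(path).read_text()
    data = None
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        pass
    if not isinstance(data, dict):
        data = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key=value")
            k, v = line.split("=", 1)
            data[k.strip()] = yaml.safe_load(v.strip())
    known = set(PipelineConfig.field_names())
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    for k in ("exclude_samples", "eligible_types", "exclude_families"):
        if k in data and isinstance(data[k], list):
            data[k] = tuple(data[k])
    return PipelineConfig(**data)
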