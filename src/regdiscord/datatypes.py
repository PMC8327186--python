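"""Shared data types for the regulon-discordance pipeline.

The pipeline operates on a genes x cells count matrix plus three annotation
tables (cells, genes, regulons) and a flat configuration object.  All
downstream modules consume these types; file parsing happens only in
:mod:`regdiscord.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "Regulon",
    "PipelineConfig",
    "make_cell_table",
    "make_gene_table",
    "ValidationError",
    "FormatError",
]


class ValidationError(ValueError):
    """Input violates a documented invariant (counts, identifiers, config)."""


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of non-negative integer UMI counts.

    Counts stay sparse throughout; column sums and nonzero counts are exposed
    without densifying.  Rows follow ``gene_ids`` order, columns ``cell_ids``.
    """

    values: sp.csc_matrix
    gene_ids: np.ndarray
    gene_symbols: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csc_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        g, c = self.values.shape
        if len(self.gene_ids) != g:
            raise ValidationError(
                f"gene identifier count {len(self.gene_ids)} != matrix rows {g}"
            )
        if len(self.gene_symbols) != g:
            raise ValidationError("gene_symbols length mismatch")
        if len(self.cell_ids) != c:
            raise ValidationError(
                f"cell identifier count {len(self.cell_ids)} != matrix columns {c}"
            )
        if len(set(self.gene_ids)) != g:
            raise ValidationError("gene_ids are not unique")
        if len(set(self.cell_ids)) != c:
            raise ValidationError("cell_ids (barcodes) are not unique")
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative count encountered")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer count encountered")

    # -- shape helpers -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cell_totals(self) -> np.ndarray:
        """UMI total per cell (column sums)."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of detected genes (count > 0) per cell."""
        return np.asarray((self.values > 0).sum(axis=0)).ravel()

    def cells_per_gene(self) -> np.ndarray:
        """Number of cells with count > 0 per gene."""
        return np.asarray((self.values > 0).sum(axis=1)).ravel()

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def cell_index(self) -> pd.Index:
        return pd.Index(self.cell_ids)

    def subset(
        self,
        genes: Sequence | None = None,
        cells: Sequence | None = None,
    ) -> "CountMatrix":
        """Return a sub-matrix restricted to the given gene/cell identifiers
        (order preserved from the argument)."""
        gi = np.arange(self.n_genes)
        ci = np.arange(self.n_cells)
        if genes is not None:
            gi = self.gene_index().get_indexer(list(genes))
            if np.any(gi < 0):
                missing = [g for g, i in zip(genes, gi) if i < 0]
                raise ValidationError(f"unknown gene ids: {missing[:5]}")
        if cells is not None:
            ci = self.cell_index().get_indexer(list(cells))
            if np.any(ci < 0):
                missing = [c for c, i in zip(cells, ci) if i < 0]
                raise ValidationError(f"unknown cell ids: {missing[:5]}")
        return CountMatrix(
            values=self.values[gi][:, ci],
            gene_ids=self.gene_ids[gi],
            gene_symbols=self.gene_symbols[gi],
            cell_ids=self.cell_ids[ci],
        )

    def row(self, gene_id) -> np.ndarray:
        """Dense count vector for one gene across all cells."""
        i = self.gene_index().get_indexer([gene_id])[0]
        if i < 0:
            raise ValidationError(f"gene {gene_id!r} not in matrix")
        return np.asarray(self.values[i].todense()).ravel()


@dataclass
class Regulon:
    """A head transcription factor plus its predicted target-gene set.

    The head is *not* implicitly a member of its own target set; if a source
    file lists it among the targets it is kept and ``head_in_targets`` records
    the fact explicitly.
    """

    head_tf: str
    targets: frozenset
    weights: Mapping[str, float] | None = None
    head_in_targets: bool = False

    def __post_init__(self) -> None:
        self.targets = frozenset(self.targets)
        if not self.targets:
            raise ValidationError(f"regulon {self.head_tf!r} has an empty target set")
        self.head_in_targets = self.head_tf in self.targets


def make_cell_table(
    cell_ids: Iterable,
    sample_id: Iterable,
    genotype: Iterable,
) -> pd.DataFrame:
    """Initial per-cell annotation table.

    QC fields (n_umis, n_genes, pct_mito) are populated by
    :func:`regdiscord.qc.compute_cell_qc`; cluster_label / cell_type / focal
    by the clustering stage.
    """
    df = pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "sample_id": list(sample_id),
            "genotype": list(genotype),
        }
    )
    bad = set(df["genotype"]) - {"WT", "KO"}
    if bad:
        raise ValidationError(f"genotype must be WT or KO, got {sorted(bad)}")
    if df["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell_id in cell table")
    for col, default in [
        ("n_umis", -1),
        ("n_genes", -1),
        ("pct_mito", np.nan),
        ("cluster_label", ""),
        ("cell_type", ""),
        ("focal", False),
        ("qc_flag", ""),
    ]:
        df[col] = default
    return df.set_index("cell_id", drop=False)


def make_gene_table(
    gene_ids: Iterable,
    symbols: Iterable,
    is_mito: Iterable | None = None,
    is_tf: Iterable | None = None,
    tf_family: Iterable | None = None,
    is_blood_marker: Iterable | None = None,
    functional_sets: Iterable | None = None,
) -> pd.DataFrame:
    """Per-gene annotation table (mito / TF / family / blood / gene sets).

    ``functional_sets`` holds, per gene, a set of gene-set names (e.g.
    ``{"neurogenesis"}``); defaults to empty sets.
    """
    gene_ids = list(gene_ids)
    n = len(gene_ids)

    def _col(x, default):
        if x is None:
            return [default] * n
        x = list(x)
        if len(x) != n:
            raise ValidationError("gene annotation column length mismatch")
        return x

    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": list(symbols),
            "is_mito": _col(is_mito, False),
            "is_tf": _col(is_tf, False),
            "tf_family": _col(tf_family, ""),
            "is_blood_marker": _col(is_blood_marker, False),
        }
    )
    if df["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene_id in gene table")
    df["functional_sets"] = [set(s) for s in _col(functional_sets, set())]
    # tf_family only meaningful for TFs
    df.loc[~df["is_tf"].astype(bool), "tf_family"] = ""
    return df.set_index("gene_id", drop=False)


@dataclass
class PipelineConfig:
    """Flat configuration mirroring the study's printed thresholds.

    QC bounds are inclusive ranges except the mitochondrial bound, which is a
    strict "< 6%"; the sample filter is strict ">500 cells"; the UMI cap is a
    strict "< 4000"; the gene filter and the detected-fraction filter are
    inclusive ">=".
    """

    qc_min_genes: int = 1000
    qc_max_genes: int = 5000
    qc_min_umis: int = 1800
    qc_max_umis: int = 10000
    qc_max_pct_mito: float = 6.0
    sample_min_cells: int = 500
    gene_min_cells: int = 3
    umi_cap: int | None = None  # e.g. 4000 for the "limited" re-analysis
    blood_fraction_threshold: float = 0.01
    exclude_samples: tuple = ()
    auc_top_fraction: float = 0.05
    binarize_rule: str = "mean"
    min_abs_delta: float = 0.3
    activity_fdr: float = 0.05
    de_fdr: float = 0.05
    de_min_abs_log2fc: float = 0.25
    min_detected_fraction: float = 0.25
    exclude_de_regulators: bool = True
    exclude_families: tuple = ()
    functional_set_filter: str | None = None
    knn_k: int = 20
    n_pcs: int = 20
    n_hvg: int = 2000
    cluster_resolution: float = 1.0
    grn_n_trees: int = 25
    grn_max_depth: int | None = 8
    grn_subsample: float = 0.9
    grn_max_cells: int = 500
    grn_max_features: float = 0.33
    grn_min_samples_leaf: int = 20
    grn_reference_genotype: str | None = "WT"
    top_n_per_tf: int = 50
    grn_min_target_share: float = 0.15
    focal_gene: str = "Satb2"
    eligible_types: tuple = (
        "intermediate_progenitor",
        "newborn_neuron",
        "deep_layer",
        "upper_layer",
    )
    use_cdr: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        pos = [
            "qc_min_genes", "qc_max_genes", "qc_min_umis", "qc_max_umis",
            "qc_max_pct_mito", "sample_min_cells", "gene_min_cells",
            "knn_k", "n_pcs", "n_hvg", "grn_n_trees", "top_n_per_tf",
        ]
        for name in pos:
            if getattr(self, name) <= 0:
                raise ValidationError(f"config field {name} must be positive")
        for name in ["auc_top_fraction", "grn_subsample"]:
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"config field {name} must be in (0, 1]")
        for name in ["min_detected_fraction", "activity_fdr", "de_fdr"]:
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"config field {name} must be in (0, 1]")
        if self.qc_min_genes > self.qc_max_genes:
            raise ValidationError("qc_min_genes > qc_max_genes")
        if self.qc_min_umis > self.qc_max_umis:
            raise ValidationError("qc_min_umis > qc_max_umis")
        if self.umi_cap is not None and self.umi_cap <= 0:
            raise ValidationError("umi_cap must be positive or None")

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def field_names(cls) -> list:
        return [f.name for f in fields(cls)]
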