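"""Normalization, highly-variable-gene selection, graph clustering, marker
annotation and focal-population selection.

The clustering path mirrors the standard single-cell PCA workflow: log2
counts-per-10k, z-scaled HVGs, PCA, cosine kNN graph, greedy modularity
community detection.  Cluster identity is assigned automatically from mean
marker z-scores, and the focal population is the cells of the eligible
neuronal types with a positive raw count of the focal gene (a Satb2-like
marker of intercortical projection neurons).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datatypes import CountMatrix, PipelineConfig, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "ClusterAssignment",
    "normalize_log_cpm",
    "select_hvg",
    "cluster_cells",
    "annotate_clusters",
    "select_focal_cells",
]


@dataclass
class NormalizedMatrix:
    """log2(1 + 10,000 * count / cell total) values, genes x cells, sparse."""

    values: sp.csc_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    hvg_flags: np.ndarray | None = None

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class ClusterAssignment:
    """Cell -> cluster labels, cluster -> cell-type names, and the marker
    score table kept for audit."""

    labels: pd.Series  # index cell_id, value cluster label (str)
    cluster_types: dict = field(default_factory=dict)
    marker_scores: pd.DataFrame | None = None

    def cell_types(self) -> pd.Series:
        return self.labels.map(lambda c: self.cluster_types.get(c, "unassigned"))


def normalize_log_cpm(counts: CountMatrix) -> NormalizedMatrix:
    """Depth-normalize to 10,000 counts per cell and log2-transform.

    Zero counts map to zero; a zero-total cell is an error (it should have
    been removed by QC).
    """
    totals = counts.cell_totals().astype(float)
    if np.any(totals == 0):
        raise ValidationError("zero-total cell present; apply QC filters first")
    x = counts.values.tocsc().astype(float).copy()
    scale = 1e4 / totals
    x = x @ sp.diags(scale)
    x.data = np.log2(1.0 + x.data)
    return NormalizedMatrix(values=sp.csc_matrix(x), gene_ids=counts.gene_ids, cell_ids=counts.cell_ids)


def select_hvg(norm: NormalizedMatrix, n_hvg: int) -> list:
    """Top genes by binned, z-scored dispersion (variance/mean, 20 mean bins).

    Dispersion is z-scored within each of 20 equal-occupancy mean bins; ties
    break lexicographically by gene_id so the selection is deterministic.
    Returns the selected gene_ids in input order; also sets ``hvg_flags``.
    """
    x = norm.values.tocsr()
    n = norm.n_cells
    mean = np.asarray(x.mean(axis=1)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=1)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * n / max(n - 1, 1)
    var[var < 1e-12] = 0.0  # numerically constant genes
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)

    # 20 equal-occupancy bins at full size; fewer for tiny inputs so each
    # bin still holds enough genes for a meaningful z-score
    n_bins = min(20, max(1, norm.n_genes // 10))
    order = np.argsort(mean, kind="mergesort")
    bins = np.empty(norm.n_genes, dtype=int)
    bins[order] = np.arange(norm.n_genes) * n_bins // norm.n_genes
    z = np.zeros(norm.n_genes)
    for b in range(n_bins):
        m = bins == b
        d = disp[m]
        sd = d.std()
        z[m] = (d - d.mean()) / sd if sd > 0 else 0.0
    # constant genes can never outrank varying ones
    z[var == 0] = -np.inf

    key = pd.DataFrame({"z": z, "gene_id": norm.gene_ids})
    key = key.sort_values(["z", "gene_id"], ascending=[False, True], kind="mergesort")
    chosen = set(key.head(n_hvg)["gene_id"])
    norm.hvg_flags = np.array([g in chosen for g in norm.gene_ids])
    return [g for g in norm.gene_ids if g in chosen]


def _scaled_pca(norm: NormalizedMatrix, cfg: PipelineConfig) -> np.ndarray:
    hvgs = norm.hvg_flags
    if hvgs is None or not hvgs.any():
        select_hvg(norm, cfg.n_hvg)
        hvgs = norm.hvg_flags
    x = np.asarray(norm.values[hvgs].todense()).T  # cells x hvgs
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = np.clip((x - mu) / sd, -10, 10)
    n_pcs = min(cfg.n_pcs, min(x.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=cfg.rng_seed)
    return pca.fit_transform(x)


def _knn_graph(coords: np.ndarray, ids, k: int, metric: str = "cosine") -> nx.Graph:
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(ids)), metric=metric)
    nn.fit(coords)
    _, idx = nn.kneighbors(coords)
    g = nx.Graph()
    g.add_nodes_from(ids)
    ids = list(ids)
    for i, row in enumerate(idx):
        for j in row[1:]:
            g.add_edge(ids[i], ids[int(j)])
    return g


def cluster_cells(norm: NormalizedMatrix, cfg: PipelineConfig) -> ClusterAssignment:
    """PCA on scaled HVGs -> cosine kNN graph -> greedy modularity communities.

    Deterministic given the configuration; labels are "c0", "c1", ... ordered
    by decreasing community size.
    """
    if norm.n_cells < cfg.knn_k + 1:
        raise ValidationError(
            f"{norm.n_cells} cells < knn_k+1 ({cfg.knn_k + 1}); reduce knn_k"
        )
    coords = _scaled_pca(norm, cfg)
    graph = _knn_graph(coords, list(norm.cell_ids), cfg.knn_k, metric="cosine")
    comms = nx.community.greedy_modularity_communities(
        graph, resolution=cfg.cluster_resolution
    )
    comms = sorted(comms, key=lambda c: (-len(c), min(map(str, c))))
    labels = {}
    for i, comm in enumerate(comms):
        for cell in comm:
            labels[cell] = f"c{i}"
    ser = pd.Series([labels[c] for c in norm.cell_ids], index=pd.Index(norm.cell_ids), name="cluster_label")
    log.info("clustering: %d cells -> %d clusters", norm.n_cells, len(comms))
    return ClusterAssignment(labels=ser)


def annotate_clusters(
    assign: ClusterAssignment,
    norm: NormalizedMatrix,
    marker_table: dict,
) -> ClusterAssignment:
    """Assign each cluster the cell type with the highest mean marker z-score.

    ``marker_table`` maps cell-type name -> iterable of marker gene ids.
    Markers absent from the matrix are skipped with a warning; an exact tie
    leaves the cluster "unassigned" with a warning.
    """
    gene_idx = norm.gene_index()
    x = norm.values.tocsr()
    mu = np.asarray(x.mean(axis=1)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=1)).ravel()
    sd = np.sqrt(np.maximum(sq - mu**2, 0.0))
    sd[sd == 0] = 1.0

    clusters = sorted(assign.labels.unique())
    cell_pos = {c: i for i, c in enumerate(norm.cell_ids)}
    cluster_cells_idx = {
        cl: np.array([cell_pos[c] for c in assign.labels.index[assign.labels == cl]])
        for cl in clusters
    }

    scores = pd.DataFrame(index=clusters, columns=sorted(marker_table), dtype=float)
    for ctype in sorted(marker_table):
        rows = gene_idx.get_indexer(list(marker_table[ctype]))
        missing = [g for g, r in zip(marker_table[ctype], rows) if r < 0]
        if missing:
            log.warning("markers for %s absent from matrix: %s", ctype, missing)
        rows = rows[rows >= 0]
        if len(rows) == 0:
            scores[ctype] = -np.inf
            continue
        sub = np.asarray(x[rows].todense())
        z = (sub - mu[rows, None]) / sd[rows, None]
        for cl in clusters:
            scores.loc[cl, ctype] = z[:, cluster_cells_idx[cl]].mean()

    types = {}
    for cl in clusters:
        row = scores.loc[cl]
        best = row.max()
        winners = sorted(row.index[row == best])
        if len(winners) != 1:
            log.warning("cluster %s: marker-score tie between %s; unassigned", cl, winners)
            types[cl] = "unassigned"
        else:
            types[cl] = winners[0]
    return ClusterAssignment(labels=assign.labels, cluster_types=types, marker_scores=scores)


def select_focal_cells(
    assign: ClusterAssignment,
    counts: CountMatrix,
    focal_gene: str,
    eligible_types,
) -> set:
    """Cells of the eligible types with a strictly positive raw count of the
    focal gene.  Raises if the resulting set is empty."""
    if focal_gene not in set(counts.gene_ids):
        raise ValidationError(f"focal gene {focal_gene!r} not in matrix")
    types = assign.cell_types()
    eligible_cells = set(types.index[types.isin(set(eligible_types))])
    expr = counts.row(focal_gene)
    positive = set(np.asarray(counts.cell_ids)[expr > 0])
    focal = eligible_cells & positive
    if not focal:
        raise ValidationError("focal cell set is empty")
    return focal
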