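"""Per-cell regulon activity: recovery-curve AUC, binarization, differential
activity, and genotype separation on binary activity profiles.

Activity of a regulon in a cell is the area under the recovery curve that
counts how many regulon targets appear among the cell's top-ranked genes
(top ``auc_top_fraction`` of the ranking), normalized to the maximum
attainable area.  Per-regulon activity is binarized at its mean AUC over all
cells (strictly greater than the mean = active).  Differential activity
between genotypes is a two-sided Fisher exact test on the 2x2
genotype x active table with BH correction, and cells are re-clustered on
binary activity profiles (Jaccard kNN graph) to quantify genotype
partitioning as neighbor purity.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import fisher_exact
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .datatypes import CountMatrix, PipelineConfig, Regulon, ValidationError
from .clustering import NormalizedMatrix

log = logging.getLogger(__name__)

__all__ = [
    "rank_genes_per_cell",
    "rank_matrix",
    "score_regulon_auc",
    "compute_activity",
    "BinaryActivity",
    "binarize_activity",
    "differential_activity",
    "recluster_binary",
    "genotype_separation",
]

_MIX = np.uint64(0x9E3779B97F4A7C15)


def _id_hash(identifier, seed: int) -> np.uint64:
    return np.uint64(zlib.crc32(f"{seed}:{identifier}".encode()))


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + _MIX).astype(np.uint64)
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x


def _tiebreak_keys(gene_ids, cell_ids, seed: int) -> np.ndarray:
    """Deterministic pseudo-random tie-break key per (gene, cell), a seeded
    hash of the identifiers only (invariant to storage order)."""
    hg = np.array([_id_hash(g, seed) for g in gene_ids], dtype=np.uint64)
    hc = np.array([_id_hash(c, seed + 1) for c in cell_ids], dtype=np.uint64)
    return _splitmix64(hg[:, None] * _MIX + hc[None, :])


def rank_genes_per_cell(values: np.ndarray, gene_ids, cell_ids, seed: int = 0) -> np.ndarray:
    """Rank genes within each cell by descending expression value.

    Returns an integer matrix of the same genes x cells shape where 1 is the
    highest-expressed gene.  Ties break by a seeded deterministic hash of
    (cell_id, gene_id), so the ranking is bit-reproducible across runs and
    independent of input row order.
    """
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    if g < 2:
        raise ValidationError("ranking needs at least two genes")
    keys = _tiebreak_keys(gene_ids, cell_ids, seed)
    ranks = np.empty((g, c), dtype=np.int32)
    for j in range(c):
        order = np.lexsort((keys[:, j], -values[:, j]))
        ranks[order, j] = np.arange(1, g + 1)
    return ranks


def rank_matrix(mat, seed: int = 0) -> pd.DataFrame:
    """Rank a CountMatrix or NormalizedMatrix; genes x cells DataFrame."""
    if isinstance(mat, (CountMatrix, NormalizedMatrix)):
        dense = np.asarray(mat.values.todense(), dtype=float)
        gene_ids, cell_ids = mat.gene_ids, mat.cell_ids
    else:
        raise ValidationError("expected CountMatrix or NormalizedMatrix")
    ranks = rank_genes_per_cell(dense, gene_ids, cell_ids, seed)
    return pd.DataFrame(ranks, index=pd.Index(gene_ids), columns=pd.Index(cell_ids))


def _max_recovery_sum(n_targets: int, k: int) -> int:
    m = min(n_targets, k)
    return m * (m + 1) // 2 + m * (k - m)


def score_regulon_auc(ranks: pd.Series, regulon: Regulon, auc_top_fraction: float) -> float:
    """Recovery-curve AUC of one regulon in one cell.

    ``ranks`` maps gene_id -> rank (1 = highest expression).  With
    k = ceil(auc_top_fraction * G), the recovery curve y_i counts regulon
    targets among the top-i ranked genes for i = 1..k and the AUC is
    sum(y_i) normalized by the maximum attainable sum given |targets| and k.
    """
    g = len(ranks)
    k = int(np.ceil(auc_top_fraction * g))
    if k < 1:
        raise ValidationError("auc_top_fraction too small: top set is empty")
    present = [t for t in regulon.targets if t in ranks.index]
    if not present:
        raise ValidationError(
            f"regulon {regulon.head_tf!r} has no targets in the ranked matrix"
        )
    r = ranks.loc[present].to_numpy()
    recovered = np.clip(k - r + 1, 0, None)
    return float(recovered.sum() / _max_recovery_sum(len(present), k))


def compute_activity(
    mat,
    regulons,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """AUC activity for every regulon in every cell (regulons x cells).

    Ranking defaults to the raw-count matrix with seeded tie-breaking; any
    genes x cells container accepted by :func:`rank_matrix` works.
    """
    ranks = rank_matrix(mat, seed=cfg.rng_seed)
    g = ranks.shape[0]
    k = int(np.ceil(cfg.auc_top_fraction * g))
    gene_pos = pd.Index(ranks.index)
    rank_arr = ranks.to_numpy()
    rows = {}
    for reg in regulons:
        pos = gene_pos.get_indexer(sorted(reg.targets))
        pos = pos[pos >= 0]
        if len(pos) == 0:
            raise ValidationError(
                f"regulon {reg.head_tf!r} has no targets in the ranked matrix"
            )
        recovered = np.clip(k - rank_arr[pos] + 1, 0, None)
        rows[reg.head_tf] = recovered.sum(axis=0) / _max_recovery_sum(len(pos), k)
    act = pd.DataFrame.from_dict(rows, orient="index", columns=ranks.columns)
    act = act.loc[sorted(rows)]
    act.attrs["auc_top_fraction"] = cfg.auc_top_fraction
    if len(act) and ((act.values < 0).any() or (act.values > 1).any()):
        raise AssertionError("AUC outside [0, 1]")
    return act


@dataclass
class BinaryActivity:
    """Regulon x cell high/low activity states with per-regulon thresholds."""

    states: pd.DataFrame  # 0/1 int
    thresholds: pd.Series


def binarize_activity(act: pd.DataFrame) -> BinaryActivity:
    """Threshold each regulon at its mean AUC over all cells (strict >).

    A constant-activity regulon is therefore "low" in every cell.
    """
    if act.shape[1] < 1:
        raise ValidationError("activity matrix has no cells")
    thresholds = act.mean(axis=1)
    states = (act.gt(thresholds, axis=0)).astype(np.int8)
    return BinaryActivity(states=states, thresholds=thresholds)


def differential_activity(
    binary: BinaryActivity,
    cells: pd.DataFrame,
    focal: set,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Per-regulon genotype x active Fisher test and three-way category.

    Category is WT_ACTIVE when delta = frac_active_wt - frac_active_ko is at
    least ``min_abs_delta`` with BH FDR below ``activity_fdr``; KO_ACTIVE is
    symmetric; otherwise NON_DIFFERENTIAL.
    """
    focal_cells = [c for c in binary.states.columns if c in focal]
    geno = cells.loc[focal_cells, "genotype"]
    wt_cells = [c for c in focal_cells if geno[c] == "WT"]
    ko_cells = [c for c in focal_cells if geno[c] == "KO"]
    if not wt_cells or not ko_cells:
        raise ValidationError("both genotypes required in the focal set")
    rows = []
    for reg in binary.states.index:
        s = binary.states.loc[reg]
        a_wt = int(s[wt_cells].sum())
        a_ko = int(s[ko_cells].sum())
        n_wt, n_ko = len(wt_cells), len(ko_cells)
        table = [[a_wt, n_wt - a_wt], [a_ko, n_ko - a_ko]]
        p = float(fisher_exact(table, alternative="two-sided")[1])
        rows.append(
            {
                "regulon": reg,
                "frac_active_wt": a_wt / n_wt,
                "frac_active_ko": a_ko / n_ko,
                "delta": a_wt / n_wt - a_ko / n_ko,
                "pvalue": p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    sig = out["fdr"] < cfg.activity_fdr
    out["category"] = "NON_DIFFERENTIAL"
    out.loc[sig & (out["delta"] >= cfg.min_abs_delta), "category"] = "WT_ACTIVE"
    out.loc[sig & (out["delta"] <= -cfg.min_abs_delta), "category"] = "KO_ACTIVE"
    return out


def recluster_binary(binary: BinaryActivity, cfg: PipelineConfig):
    """kNN graph on Jaccard distance between cells' binary activity profiles.

    Returns (graph, embedding DataFrame).  The graph is deterministic; the
    2-D embedding (PCA of the binary profiles) is for plotting only.
    """
    profiles = binary.states.to_numpy().T.astype(bool)  # cells x regulons
    cells = list(binary.states.columns)
    if len(cells) < cfg.knn_k + 1:
        raise ValidationError("fewer cells than knn_k + 1")
    empty = ~profiles.any(axis=1)
    if empty.any():
        log.warning("%d cells have all-zero activity profiles", int(empty.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = squareform(pdist(profiles, metric="jaccard"))
    dist = np.nan_to_num(dist, nan=0.0)
    np.fill_diagonal(dist, np.inf)
    graph = nx.Graph()
    graph.add_nodes_from(cells)
    # ties at equal distance resolved by cell identifier, so the graph is
    # invariant to the storage order of cells
    id_rank = np.argsort(np.argsort([str(c) for c in cells]))
    for i in range(len(cells)):
        order = np.lexsort((id_rank, dist[i]))[: cfg.knn_k]
        for j in order:
            graph.add_edge(cells[i], cells[int(j)])
    emb = PCA(n_components=2, svd_solver="full", random_state=cfg.rng_seed).fit_transform(
        profiles.astype(float)
    )
    embedding = pd.DataFrame(emb, index=pd.Index(cells), columns=["dim1", "dim2"])
    return graph, embedding


def genotype_separation(graph: nx.Graph, cells: pd.DataFrame) -> float:
    """Mean over cells of the fraction of graph neighbors sharing the cell's
    genotype; 1.0 means perfect genotype partitioning, 0.5 chance for
    balanced classes."""
    geno = cells["genotype"]
    fracs = []
    for node in graph.nodes:
        nbrs = list(graph.neighbors(node))
        if not nbrs:
            continue
        same = sum(geno[n] == geno[node] for n in nbrs)
        fracs.append(same / len(nbrs))
    return float(np.mean(fracs)) if fracs else 0.0
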