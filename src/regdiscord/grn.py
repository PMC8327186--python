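"""Co-expression regulon inference: tree-ensemble TF -> target importances.

For each target gene an ensemble of extremely-randomized regression trees
predicts its normalized expression from all TF expressions; each TF's total
impurity-reduction importance is recorded.  Regulons are then the top-n
targets per TF.  No motif pruning is applied; motif-pruned regulons can be
supplied externally as GMT instead.
"""

from __future__ import annotations

import logging
import zlib

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor

from .clustering import NormalizedMatrix
from .datatypes import PipelineConfig, Regulon, ValidationError

log = logging.getLogger(__name__)

__all__ = ["infer_tf_importance", "build_regulons"]


def _raw_importances(est: ExtraTreesRegressor) -> np.ndarray:
    """Mean unnormalized impurity-reduction importance over the ensemble
    (variance-reduction units, not rescaled to sum to 1)."""
    return np.mean(
        [t.tree_.compute_feature_importances(normalize=False) for t in est.estimators_],
        axis=0,
    )


def infer_tf_importance(
    norm: NormalizedMatrix,
    tf_list,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """TF x target importance matrix from per-target tree ensembles.

    Self-importance (TF predicting itself) is masked to 0.  Deterministic
    given ``cfg.rng_seed``; cells are subsampled once (without replacement)
    to at most ``cfg.grn_max_cells`` to keep ensembles desk-scale.
    """
    tf_list = [t for t in tf_list if t in set(norm.gene_ids)]
    if len(tf_list) < 2:
        raise ValidationError("need at least two TFs present in the matrix")
    tf_list = sorted(tf_list)
    gene_idx = norm.gene_index()
    tf_rows = gene_idx.get_indexer(tf_list)

    rng = np.random.default_rng(cfg.rng_seed)
    n_cells = norm.n_cells
    if n_cells > cfg.grn_max_cells:
        cell_sel = np.sort(rng.choice(n_cells, size=cfg.grn_max_cells, replace=False))
    else:
        cell_sel = np.arange(n_cells)

    dense = np.asarray(norm.values[:, cell_sel].todense())
    X_tf = dense[tf_rows].T  # cells x TFs
    targets = list(norm.gene_ids)
    imp = np.zeros((len(tf_list), len(targets)))
    tf_pos = {t: i for i, t in enumerate(tf_list)}

    n_sub = max(2, int(round(cfg.grn_subsample * len(cell_sel))))
    # at least two candidate features per split, else leaf-size rejection of
    # the single candidate prunes whole trees to stumps
    n_feat = max(2, min(len(tf_list) - 1, int(round(cfg.grn_max_features * len(tf_list)))))
    for j, gene in enumerate(targets):
        y = dense[gene_idx.get_loc(gene)]
        sd = y.std()
        if sd == 0:
            continue
        y = (y - y.mean()) / sd  # unit variance makes importances comparable across targets
        est = ExtraTreesRegressor(
            n_estimators=cfg.grn_n_trees,
            max_depth=cfg.grn_max_depth,
            min_samples_leaf=cfg.grn_min_samples_leaf,
            max_features=n_feat,
            bootstrap=True,
            max_samples=n_sub,
            random_state=(cfg.rng_seed * 2654435761 + zlib.crc32(str(gene).encode()))
            % (2**31),
            n_jobs=1,
        )
        if gene in tf_pos:
            keep = [i for i in range(len(tf_list)) if i != tf_pos[gene]]
            est.fit(X_tf[:, keep], y)
            imp[keep, j] = _raw_importances(est)
        else:
            est.fit(X_tf, y)
            imp[:, j] = _raw_importances(est)
    imp = np.nan_to_num(imp, nan=0.0)
    out = pd.DataFrame(imp, index=pd.Index(tf_list, name="tf"), columns=targets)
    out.attrs["n_trees"] = cfg.grn_n_trees
    out.attrs["seed"] = cfg.rng_seed
    return out


def build_regulons(
    imp: pd.DataFrame,
    top_n_per_tf: int = 50,
    min_target_share: float = 0.0,
) -> list[Regulon]:
    """Each TF's regulon is its top-n targets by importance (ties by gene_id).

    A TF whose importance row is all zero yields no regulon; zero-importance
    targets are never included.  ``min_target_share`` additionally requires
    the TF to hold at least that fraction of a target's total importance
    across all TFs -- a pruning surrogate standing in for motif-based target
    refinement, which keeps weakly attributed genes (library/composition
    artifacts shared by every TF) out of the regulon.
    """
    if top_n_per_tf < 1:
        raise ValidationError("top_n_per_tf must be >= 1")
    colsum = imp.sum(axis=0)
    regulons = []
    for tf in imp.index:
        row = imp.loc[tf].drop(labels=[tf], errors="ignore")
        row = row[row > 0]
        if min_target_share > 0 and len(row):
            share = row / colsum[row.index].replace(0.0, np.inf)
            row = row[share >= min_target_share]
        if row.empty:
            continue
        ordered = row.to_frame("imp").reset_index(names="gene")
        ordered = ordered.sort_values(["imp", "gene"], ascending=[False, True], kind="mergesort")
        top = ordered.head(top_n_per_tf)
        weights = dict(zip(top["gene"], top["imp"]))
        regulons.append(Regulon(head_tf=tf, targets=frozenset(top["gene"]), weights=weights))
    return regulons
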