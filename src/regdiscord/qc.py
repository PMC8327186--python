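"""Cell-, gene- and sample-level quality filters.

Thresholds follow the study design they reproduce: 1000-5000 detected genes
per cell and 1800-10,000 UMIs (both inclusive), mitochondrial fraction
strictly below 6%, samples kept only with strictly more than 500 surviving
cells, genes kept when detected in at least 3 retained cells, and an
optional strict UMI cap (<4000) for a depth-matched sensitivity re-analysis.
Filter composition is cells -> background -> samples -> genes; re-running
the composed filter on its own output is a fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, PipelineConfig, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "compute_cell_qc",
    "filter_cells",
    "flag_background_cells",
    "filter_samples",
    "filter_genes",
    "apply_umi_cap",
    "run_qc",
]


@dataclass
class QCReport:
    """Bookkeeping for the QC stage: what was removed, where, and why."""

    cells_before: int = 0
    cells_after: int = 0
    removal_reasons: dict = field(default_factory=dict)
    per_sample_before: dict = field(default_factory=dict)
    per_sample_after: dict = field(default_factory=dict)
    dropped_samples: list = field(default_factory=list)
    flagged_background: list = field(default_factory=list)
    genes_before: int = 0
    genes_after: int = 0

    def add_removals(self, reason: str, n: int) -> None:
        if n:
            self.removal_reasons[reason] = self.removal_reasons.get(reason, 0) + n

    @property
    def total_removed(self) -> int:
        return sum(self.removal_reasons.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("cells_before", self.cells_before), ("cells_after", self.cells_after)]
        rows += [(f"removed_{k}", v) for k, v in sorted(self.removal_reasons.items())]
        rows += [("genes_before", self.genes_before), ("genes_after", self.genes_after)]
        rows += [("dropped_samples", ";".join(map(str, self.dropped_samples)))]
        return pd.DataFrame(rows, columns=["metric", "value"])


def compute_cell_qc(counts: CountMatrix, genes: pd.DataFrame) -> pd.DataFrame:
    """Populate n_umis, n_genes and pct_mito on a fresh per-cell table.

    pct_mito is 100 * (mito-gene counts / total counts), defined as 0 for an
    all-zero cell (which is flagged rather than erroring).
    """
    missing = set(counts.gene_ids) - set(genes["gene_id"])
    if missing:
        raise ValidationError(f"gene table missing ids: {sorted(missing)[:5]}")
    aligned = genes.loc[list(counts.gene_ids)]
    mito_mask = aligned["is_mito"].to_numpy(dtype=bool)

    totals = counts.cell_totals().astype(np.int64)
    n_genes = counts.genes_per_cell().astype(np.int64)
    mito_counts = np.asarray(counts.values[mito_mask].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * mito_counts / np.maximum(totals, 1), 0.0)

    df = pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "n_umis": totals,
            "n_genes": n_genes,
            "pct_mito": pct,
            "qc_flag": np.where(totals == 0, "all_zero", ""),
        }
    ).set_index("cell_id", drop=False)
    return df


def filter_cells(cells: pd.DataFrame, cfg: PipelineConfig):
    """Apply the per-cell thresholds; returns (retained cell ids, QCReport).

    Gene and UMI bounds are inclusive ranges; the mito bound is strict.
    A cell failing several criteria is charged to the first in the order
    genes, umis, mito.
    """
    if (cells["n_umis"] < 0).any():
        raise ValidationError("QC fields not populated; run compute_cell_qc first")
    report = QCReport(cells_before=len(cells))
    g = cells["n_genes"].to_numpy()
    u = cells["n_umis"].to_numpy()
    m = cells["pct_mito"].to_numpy()
    ok_genes = (g >= cfg.qc_min_genes) & (g <= cfg.qc_max_genes)
    ok_umis = (u >= cfg.qc_min_umis) & (u <= cfg.qc_max_umis)
    ok_mito = m < cfg.qc_max_pct_mito
    keep = ok_genes & ok_umis & ok_mito
    report.add_removals("genes", int((~ok_genes).sum()))
    report.add_removals("umis", int((ok_genes & ~ok_umis).sum()))
    report.add_removals("mito", int((ok_genes & ok_umis & ~ok_mito).sum()))
    report.cells_after = int(keep.sum())
    retained = set(cells.loc[keep, "cell_id"])
    return retained, report


def flag_background_cells(
    counts: CountMatrix,
    cells: pd.DataFrame,
    genes: pd.DataFrame,
    score_threshold: float = 0.01,
) -> set:
    """Flag cells whose blood-marker count fraction exceeds the threshold.

    Emulates the exclusion of cells with high background expression of
    blood-related genes (hemoglobins etc.).  With no blood markers annotated
    this is a no-op with a warning.
    """
    aligned = genes.loc[list(counts.gene_ids)]
    blood_mask = aligned["is_blood_marker"].to_numpy(dtype=bool)
    if not blood_mask.any():
        log.warning("no blood-marker genes annotated; background flagging skipped")
        return set()
    totals = counts.cell_totals().astype(float)
    blood = np.asarray(counts.values[blood_mask].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, blood / np.maximum(totals, 1), 0.0)
    flagged = frac > score_threshold
    return set(np.asarray(counts.cell_ids)[flagged])


def filter_samples(cells: pd.DataFrame, cfg: PipelineConfig):
    """Keep samples with strictly more than ``sample_min_cells`` cells.

    ``cells`` must already be restricted to QC-passing cells.  Raises if no
    sample survives.
    """
    report = QCReport(cells_before=len(cells))
    sizes = cells.groupby("sample_id").size()
    keep = sizes[sizes > cfg.sample_min_cells].index
    report.per_sample_before = sizes.to_dict()
    report.dropped_samples = sorted(set(sizes.index) - set(keep))
    if len(keep) == 0:
        raise ValidationError("no samples survive QC")
    kept_cells = cells[cells["sample_id"].isin(keep)]
    report.per_sample_after = kept_cells.groupby("sample_id").size().to_dict()
    report.cells_after = len(kept_cells)
    report.add_removals("sample_too_small", report.cells_before - report.cells_after)
    return set(keep), report


def filter_genes(counts: CountMatrix, cfg: PipelineConfig) -> set:
    """Keep genes detected (count>0) in at least ``gene_min_cells`` cells."""
    keep = counts.cells_per_gene() >= cfg.gene_min_cells
    return set(np.asarray(counts.gene_ids)[keep])


def apply_umi_cap(cells: pd.DataFrame, cap: int | None) -> set:
    """Keep cells with strictly fewer UMIs than ``cap``; identity if cap is None."""
    if cap is None:
        return set(cells["cell_id"])
    if cap <= 0:
        raise ValidationError("umi cap must be positive")
    return set(cells.loc[cells["n_umis"] < cap, "cell_id"])


def run_qc(counts: CountMatrix, cells: pd.DataFrame, genes: pd.DataFrame, cfg: PipelineConfig):
    """Composed QC: cell thresholds -> background flag -> manual sample
    exclusions -> sample size filter -> gene filter -> optional UMI cap.

    Returns (filtered CountMatrix, filtered cell table, QCReport).
    """
    qc = compute_cell_qc(counts, genes)
    for col in ["n_umis", "n_genes", "pct_mito", "qc_flag"]:
        cells = cells.copy()
        cells[col] = qc[col]
    report = QCReport(cells_before=len(cells), genes_before=counts.n_genes)
    report.per_sample_before = cells.groupby("sample_id").size().to_dict()

    retained, cell_rep = filter_cells(cells, cfg)
    report.removal_reasons.update(cell_rep.removal_reasons)

    background = flag_background_cells(counts, cells, genes, cfg.blood_fraction_threshold)
    newly = background & retained
    report.flagged_background = sorted(newly)
    report.add_removals("blood_background", len(newly))
    retained -= background

    if cfg.exclude_samples:
        excl = cells["sample_id"].isin(cfg.exclude_samples) & cells["cell_id"].isin(retained)
        report.add_removals("manual_sample_exclusion", int(excl.sum()))
        retained -= set(cells.loc[excl, "cell_id"])

    kept_cells = cells[cells["cell_id"].isin(retained)]
    kept_samples, samp_rep = filter_samples(kept_cells, cfg)
    report.removal_reasons.update(samp_rep.removal_reasons)
    report.dropped_samples = samp_rep.dropped_samples
    kept_cells = kept_cells[kept_cells["sample_id"].isin(kept_samples)]

    if cfg.umi_cap is not None:
        capped = apply_umi_cap(kept_cells, cfg.umi_cap)
        report.add_removals("umi_cap", len(kept_cells) - len(capped))
        kept_cells = kept_cells[kept_cells["cell_id"].isin(capped)]

    sub = counts.subset(cells=kept_cells["cell_id"])
    kept_genes = filter_genes(sub, cfg)
    gene_order = [g for g in counts.gene_ids if g in kept_genes]
    sub = sub.subset(genes=gene_order)

    report.cells_after = len(kept_cells)
    report.genes_after = sub.n_genes
    report.per_sample_after = kept_cells.groupby("sample_id").size().to_dict()
    log.info(
        "QC: %d -> %d cells, %d -> %d genes, dropped samples: %s",
        report.cells_before, report.cells_after,
        report.genes_before, report.genes_after, report.dropped_samples,
    )
    return sub, kept_cells, report
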