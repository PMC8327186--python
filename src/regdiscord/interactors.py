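"""Discordance classification of regulon heads as candidate interactors.

A regulon head is nominated as a candidate physical interactor of the
perturbed TF when its regulon is differentially active between genotypes
while the head itself is *not* differentially expressed (the discordance
criterion: activity collapses without a change in the regulator, arguing
against a simple downstream-target relationship), is robustly expressed
(detected in at least a quarter of the focal cells), and optionally belongs
to a configured functional gene set (e.g. neurogenesis / neuron
differentiation).  The bHLH-vs-other family split is reported, not used as
a filter, by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, PipelineConfig, Regulon, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "compute_detected_fraction",
    "classify_candidates",
    "tally_families",
    "intersect_common_targets",
]


def compute_detected_fraction(counts: CountMatrix, focal: set, gene) -> float:
    """Fraction of focal cells with a raw count > 0 for ``gene``."""
    if not focal:
        raise ValidationError("focal cell set is empty")
    expr = counts.row(gene)  # raises if absent
    mask = np.array([c in focal for c in counts.cell_ids])
    return float((expr[mask] > 0).mean())


def _is_de_call(row: pd.Series, cfg: PipelineConfig) -> bool:
    return bool(row["fdr"] < cfg.de_fdr and abs(row["log2fc"]) > cfg.de_min_abs_log2fc)


def classify_candidates(
    differentials: pd.DataFrame,
    de_results: pd.DataFrame,
    genes: pd.DataFrame,
    counts: CountMatrix,
    focal: set,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Apply the candidate-interactor gates to every scored regulon head.

    Gates: differentially active regulon; head not differentially expressed
    (when ``exclude_de_regulators``); head detected in at least
    ``min_detected_fraction`` of focal cells; head in the configured
    functional gene set (when ``functional_set_filter`` is set); head's TF
    family not in ``exclude_families`` (empty by default -- the family split
    is reported, not filtered).
    """
    de_idx = de_results.set_index("gene_id") if len(de_results) else pd.DataFrame()
    matrix_genes = set(counts.gene_ids)
    rows = []
    for _, d in differentials.iterrows():
        tf = d["regulon"]
        fail = []
        if d["category"] == "NON_DIFFERENTIAL":
            fail.append("not differentially active")
        regulator_is_de = False
        if tf in getattr(de_idx, "index", []):
            regulator_is_de = _is_de_call(de_idx.loc[tf], cfg)
        else:
            log.warning("regulon head %s missing from DE results; treated as not-DE", tf)
        if cfg.exclude_de_regulators and regulator_is_de:
            fail.append("regulator differentially expressed")
        if tf in matrix_genes:
            frac = compute_detected_fraction(counts, focal, tf)
        else:
            frac = 0.0
            log.warning("regulon head %s absent from count matrix", tf)
        if frac < cfg.min_detected_fraction:
            fail.append("detected fraction below threshold")
        family = ""
        in_set = False
        if tf in genes.index:
            family = genes.loc[tf, "tf_family"]
            fsets = genes.loc[tf, "functional_sets"]
            in_set = bool(cfg.functional_set_filter in fsets) if cfg.functional_set_filter else False
        if cfg.functional_set_filter and not in_set:
            fail.append("not in functional gene set")
        if family and family in cfg.exclude_families:
            fail.append("excluded TF family")
        rows.append(
            {
                "tf": tf,
                "category": d["category"],
                "delta": d["delta"],
                "activity_fdr": d["fdr"],
                "regulator_is_de": regulator_is_de,
                "detected_fraction": frac,
                "tf_family": family,
                "in_functional_set": in_set,
                "passes": not fail,
                "fail_reasons": ";".join(fail),
            }
        )
    return pd.DataFrame(rows)


def tally_families(calls: pd.DataFrame) -> pd.DataFrame:
    """Percentages of differentially active regulon heads that are bHLH vs
    other, and DE vs not-DE (each pair summing to 100%)."""
    if not len(calls):
        return pd.DataFrame(columns=["metric", "pct"])
    da = calls[calls["category"] != "NON_DIFFERENTIAL"]
    n = len(da)
    if n == 0:
        return pd.DataFrame(columns=["metric", "pct"])
    n_bhlh = int((da["tf_family"].str.lower() == "bhlh").sum())
    n_de = int(da["regulator_is_de"].sum())
    rows = [
        ("bHLH", round(100.0 * n_bhlh / n, 2)),
        ("other", round(100.0 * (n - n_bhlh) / n, 2)),
        ("DE", round(100.0 * n_de / n, 2)),
        ("not_DE", round(100.0 * (n - n_de) / n, 2)),
    ]
    return pd.DataFrame(rows, columns=["metric", "pct"])


def intersect_common_targets(de_results: pd.DataFrame, regulon: Regulon) -> pd.DataFrame:
    """DEGs intersected with a partner regulon's predicted targets.

    Returns a sorted one-gene-per-row table; attrs record both input sizes.
    """
    degs = set(de_results.loc[de_results["is_de"], "gene_id"]) if len(de_results) else set()
    common = sorted(degs & set(regulon.targets))
    out = pd.DataFrame({"partner_tf": regulon.head_tf, "gene": common})
    out.attrs["n_degs"] = len(degs)
    out.attrs["n_targets"] = len(regulon.targets)
    return out
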