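"""End-to-end orchestration: QC -> clustering -> focal subset -> DE -> GRN ->
regulon activity -> interactor calls, with a run manifest and TSV reports.

``run_pipeline`` is deterministic given the config seed; the expensive
GRN-importance stage is cached on a digest of its inputs so late stages can
be iterated without recomputing it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import (
    binarize_activity,
    compute_activity,
    differential_activity,
    genotype_separation,
    recluster_binary,
)
from .clustering import (
    annotate_clusters,
    cluster_cells,
    normalize_log_cpm,
    select_focal_cells,
    select_hvg,
)
from .datatypes import CountMatrix, PipelineConfig, ValidationError
from .de import run_de
from .grn import build_regulons, infer_tf_importance
from .interactors import classify_candidates, intersect_common_targets, tally_families
from .io import write_report_tables
from .qc import run_qc

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "summarize_run", "RunManifest", "PipelineResults"]


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True, default=str)


@dataclass
class PipelineResults:
    counts: CountMatrix
    cells: pd.DataFrame
    qc_report: object
    assignment: object
    focal: set
    de_table: pd.DataFrame
    regulons: list
    activity: pd.DataFrame
    binary: object
    regulon_differential: pd.DataFrame
    interactor_calls: pd.DataFrame
    family_tally: pd.DataFrame
    common_targets: pd.DataFrame
    separation: float
    manifest: RunManifest

    @property
    def passing_tfs(self) -> list:
        t = self.interactor_calls
        return sorted(t.loc[t["passes"], "tf"]) if len(t) else []


def _digest(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes() if isinstance(a, np.ndarray) else str(a).encode())
    return h.hexdigest()[:16]


def run_pipeline(
    counts: CountMatrix,
    cells: pd.DataFrame,
    genes: pd.DataFrame,
    cfg: PipelineConfig,
    marker_table: dict,
    out_dir,
    regulons: list | None = None,
) -> PipelineResults:
    """Run every stage on an in-memory dataset and write report TSVs.

    ``regulons`` may be supplied (e.g. parsed from GMT) to skip co-expression
    inference.  ``marker_table`` maps cell-type name -> marker gene ids.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg.to_dict(), seed=cfg.rng_seed,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    manifest.input_digests = {
        "counts": _digest(counts.values.data, counts.values.indices,
                          counts.gene_ids.astype(str), counts.cell_ids.astype(str)),
        "config": _digest(json.dumps(cfg.to_dict(), sort_keys=True)),
    }
    manifest.stage_counts["input"] = {"cells": counts.n_cells, "genes": counts.n_genes}

    # ---- QC ----------------------------------------------------------
    counts_f, cells_f, qc_report = run_qc(counts, cells, genes, cfg)
    manifest.stage_counts["qc"] = {"cells": counts_f.n_cells, "genes": counts_f.n_genes}

    # ---- clustering and annotation ----------------------------------
    norm = normalize_log_cpm(counts_f)
    select_hvg(norm, cfg.n_hvg)
    assign = cluster_cells(norm, cfg)
    assign = annotate_clusters(assign, norm, marker_table)
    cells_f = cells_f.copy()
    cells_f["cluster_label"] = assign.labels.reindex(cells_f.index)
    cells_f["cell_type"] = assign.cell_types().reindex(cells_f.index)
    manifest.stage_counts["clustering"] = {
        "cells": counts_f.n_cells, "clusters": int(assign.labels.nunique()),
    }

    # ---- focal population -------------------------------------------
    focal = select_focal_cells(assign, counts_f, cfg.focal_gene, cfg.eligible_types)
    cells_f["focal"] = cells_f["cell_id"].isin(focal)
    n_focal_by_geno = cells_f.loc[cells_f["focal"]].groupby("genotype").size().to_dict()
    manifest.stage_counts["focal"] = {"cells": len(focal), **n_focal_by_geno}
    log.info("focal population: %d cells (%s)", len(focal), n_focal_by_geno)

    # ---- differential expression ------------------------------------
    de_table = run_de(counts_f, cells_f, focal, cfg)
    manifest.stage_counts["de"] = {
        "genes": len(de_table), "degs": int(de_table["is_de"].sum()) if len(de_table) else 0,
    }

    # ---- regulons ----------------------------------------------------
    focal_order = [c for c in counts_f.cell_ids if c in focal]
    focal_counts = counts_f.subset(cells=focal_order)
    if regulons is None:
        tf_list = sorted(set(genes.loc[genes["is_tf"].astype(bool), "gene_id"])
                         & set(focal_counts.gene_ids))
        # network inferred on the reference genotype so perturbation-driven
        # covariation cannot masquerade as co-expression edges
        grn_cells = focal_order
        if cfg.grn_reference_genotype:
            grn_cells = [c for c in focal_order
                         if cells_f.loc[c, "genotype"] == cfg.grn_reference_genotype]
        grn_norm = normalize_log_cpm(counts_f.subset(cells=grn_cells))
        imp = _cached_importance(grn_norm, tf_list, cfg, out)
        regulons = build_regulons(imp, cfg.top_n_per_tf, cfg.grn_min_target_share)
    manifest.stage_counts["grn"] = {"regulons": len(regulons)}

    # ---- regulon activity -------------------------------------------
    act = compute_activity(focal_counts, regulons, cfg)
    binary = binarize_activity(act)
    diff = differential_activity(binary, cells_f, focal, cfg)
    graph, embedding = recluster_binary(binary, cfg)
    separation = genotype_separation(graph, cells_f)
    manifest.stage_counts["activity"] = {
        "regulons": len(act),
        "differential": int((diff["category"] != "NON_DIFFERENTIAL").sum()),
    }

    # ---- interactor calls -------------------------------------------
    calls = classify_candidates(diff, de_table, genes, focal_counts, focal, cfg)
    tally = tally_families(calls)
    common_parts = []
    reg_by_tf = {r.head_tf: r for r in regulons}
    for tf in sorted(calls.loc[calls["passes"], "tf"]) if len(calls) else []:
        common_parts.append(intersect_common_targets(de_table, reg_by_tf[tf]))
    common = (pd.concat(common_parts, ignore_index=True) if common_parts
              else pd.DataFrame(columns=["partner_tf", "gene"]))
    manifest.stage_counts["interactors"] = {
        "candidates": len(calls),
        "passing": int(calls["passes"].sum()) if len(calls) else 0,
    }

    # ---- reports -----------------------------------------------------
    write_report_tables(
        {
            "de": de_table,
            "regulon_differential": diff,
            "interactor_calls": calls,
            "common_targets": common,
            "family_tally": tally,
        },
        out,
    )
    qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    embedding.round(6).to_csv(out / "binary_embedding.tsv", sep="\t")
    with open(out / "separation.txt", "w") as fh:
        fh.write(f"{separation:.6f}\n")
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(manifest.to_json())

    return PipelineResults(
        counts=counts_f, cells=cells_f, qc_report=qc_report, assignment=assign,
        focal=focal, de_table=de_table, regulons=regulons, activity=act,
        binary=binary, regulon_differential=diff, interactor_calls=calls,
        family_tally=tally, common_targets=common, separation=separation,
        manifest=manifest,
    )


def _cached_importance(norm, tf_list, cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    key = _digest(
        np.asarray(norm.values.data), np.asarray(norm.values.indices),
        ",".join(map(str, tf_list)),
        cfg.grn_n_trees, cfg.grn_max_depth, cfg.grn_subsample,
        cfg.grn_max_cells, cfg.rng_seed,
    )
    cache = out / "cache" / f"importance_{key}.tsv"
    if cache.exists():
        log.info("GRN importance cache hit: %s", cache.name)
        return pd.read_csv(cache, sep="\t", index_col=0)
    imp = infer_tf_importance(norm, tf_list, cfg)
    cache.parent.mkdir(parents=True, exist_ok=True)
    imp.to_csv(cache, sep="\t")
    return imp


def summarize_run(out_dir) -> str:
    """Human-readable summary recomputed from the written report tables."""
    out = Path(out_dir)
    needed = ["de.tsv", "regulon_differential.tsv", "interactor_calls.tsv",
              "common_targets.tsv"]
    for name in needed:
        if not (out / name).exists():
            raise FileNotFoundError(f"missing report table: {name}")
    de = pd.read_csv(out / "de.tsv", sep="\t")
    diff = pd.read_csv(out / "regulon_differential.tsv", sep="\t")
    calls = pd.read_csv(out / "interactor_calls.tsv", sep="\t")
    common = pd.read_csv(out / "common_targets.tsv", sep="\t")
    n_up = int(((de["is_de"]) & (de["log2fc"] > 0)).sum()) if len(de) else 0
    n_dn = int(((de["is_de"]) & (de["log2fc"] < 0)).sum()) if len(de) else 0
    cats = diff["category"].value_counts().to_dict() if len(diff) else {}
    passing = sorted(calls.loc[calls["passes"].astype(bool), "tf"]) if len(calls) else []
    da = calls[calls["category"] != "NON_DIFFERENTIAL"] if len(calls) else calls
    lines = [
        f"regdiscord run summary ({out})",
        f"  DEGs: {n_up + n_dn} ({n_up} up, {n_dn} down in KO)",
        "  regulon categories: "
        + ", ".join(f"{k}={cats.get(k, 0)}" for k in
                    ["WT_ACTIVE", "NON_DIFFERENTIAL", "KO_ACTIVE"]),
    ]
    if len(da):
        pct_bhlh = 100.0 * (da["tf_family"].astype(str).str.lower() == "bhlh").mean()
        pct_de = 100.0 * da["regulator_is_de"].astype(bool).mean()
        lines.append(
            f"  differentially active heads: {len(da)} "
            f"(bHLH {pct_bhlh:.2f}%, regulator-DE {pct_de:.2f}%)"
        )
    lines.append(f"  passing interactor candidates: {len(passing)}"
                 + (f" ({', '.join(passing)})" if passing else ""))
    lines.append(f"  common DEG/regulon targets listed: {len(common)}")
    sep_file = out / "separation.txt"
    if sep_file.exists():
        lines.append(f"  genotype neighbor purity: {float(sep_file.read_text()):.3f}")
    return "\n".join(lines)
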