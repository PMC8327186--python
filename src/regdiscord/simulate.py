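"""Seeded generator of WT/KO scRNA-seq datasets with planted ground truth.

The generator emulates a two-genotype embryonic-neocortex experiment: several
samples per genotype, a handful of marker-defined cell types including a
focal Satb2-expressing projection-neuron population, negative-binomial counts
with per-cell log-normal library factors (systematically lower in the KO),
mitochondrial and blood-contamination genes, deliberate QC-violating cells,
and -- the point of the exercise -- planted "partner" TFs whose regulon
targets are multiplicatively suppressed in KO focal cells while the TF's own
expression is untouched, next to decoy TFs that are themselves differentially
expressed (their regulons following them down).  Every TF's targets are
coupled to a per-cell latent activity of the TF, which is what makes
co-expression regulon inference possible on the synthetic data.

All draws come from one seeded generator; the same seed reproduces the
dataset bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CountMatrix, Regulon, ValidationError, make_cell_table, make_gene_table
from . import io as rio

__all__ = ["ScenarioConfig", "SyntheticTruth", "generate_dataset", "write_fixture",
           "simulate_de_dataset", "null_scenario"]

_CANONICAL_TYPES = [
    "intermediate_progenitor", "newborn_neuron", "deep_layer", "upper_layer",
    "interneuron", "astrocyte", "microglia", "endothelial",
]
_TYPE_PROPS = [0.10, 0.15, 0.15, 0.25, 0.10, 0.10, 0.08, 0.07]
_ELIGIBLE = set(_CANONICAL_TYPES[:4])
_FAMILIES = ["SOX", "FOX", "POU", "other"]


@dataclass
class ScenarioConfig:
    """Study conditions for the synthetic experiment (defaults emulate the
    E18.5 neocortex design: 2 genotypes x 3 samples x ~800 cells)."""

    n_samples: int = 3              # per genotype
    cells_per_sample: int = 800
    cell_jitter: int = 50
    n_genes: int = 2500
    n_cell_types: int = 8
    n_tfs: int = 40
    regulon_size: int = 30
    n_partner_tfs: int = 5
    partner_scaling: float = 0.4    # f: KO focal multiplier on partner targets
    n_decoy_de_tfs: int = 3
    decoy_expression_factor: float = 0.4
    n_planted_degs: int = 40
    deg_fold_change: float = 2.0
    dispersion: float = 0.5         # NB at low expression: var = mu + dispersion * mu^2
    dispersion_floor: float = 0.15  # asymptotic dispersion of highly expressed genes
    dispersion_scale: float = 4.0   # mean at which dispersion decays toward the floor
    lib_sigma: float = 0.25
    ko_lib_factor: float = 0.85     # KO library-size shift (lower depth)
    n_mito_genes: int = 10
    mito_gene_mean: float = 6.0
    n_blood_genes: int = 5
    contamination_fraction: float = 0.02
    contamination_blood_mean: float = 30.0
    low_quality_fraction: float = 0.04
    n_tier_genes: int = 80          # broadly high-expressed genes (rank competition)
    tier_median: float = 8.0
    tier_sigma: float = 0.4
    background_mean: float = 1.0
    n_buffer_genes: int = 150       # mid-expression genes absorbing freed top ranks
    buffer_mean: float = 3.5
    active_target_mean: float = 4.5
    marker_mean: float = 4.0
    marker_off_mean: float = 0.2
    markers_per_type: int = 15
    tf_base_mean: float = 1.5
    active_tf_mean: float = 6.0
    tf_latent_sigma: float = 0.4    # lognormal latent for non-program TFs
    target_coupling: float = 1.4
    program_on_prob: float = 0.6    # per-cell firing probability of active programs
    program_off_target_factor: float = 0.15
    program_off_tf_factor: float = 0.4
    deg_base_mean: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cell_types < 4 or self.n_cell_types > len(_CANONICAL_TYPES):
            raise ValidationError("n_cell_types must be between 4 and 8")
        if not (0 < self.partner_scaling <= 1):
            raise ValidationError("partner_scaling must be in (0, 1]")
        if self.n_partner_tfs + self.n_decoy_de_tfs > self.n_tfs:
            raise ValidationError("more planted TFs than TFs")
        fixed = (self.n_mito_genes + self.n_blood_genes + 1 + self.n_tfs
                 + self.n_cell_types * self.markers_per_type
                 + self.n_tfs * self.regulon_size + self.n_tier_genes + self.n_buffer_genes
                 + self.n_planted_degs)
        if fixed > self.n_genes:
            raise ValidationError(
                f"gene budget exceeded: {fixed} structured genes > n_genes={self.n_genes}"
            )
        for name in ("dispersion", "lib_sigma", "ko_lib_factor"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def null_scenario(**overrides) -> ScenarioConfig:
    """The no-effect control: f = 1, no decoys, no planted DEGs, equal
    library-size distributions in both genotypes."""
    base = dict(partner_scaling=1.0, n_partner_tfs=0, n_decoy_de_tfs=0,
                n_planted_degs=0, ko_lib_factor=1.0)
    base.update(overrides)
    return ScenarioConfig(**base)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    planted_partner_tfs: list
    planted_de_tfs: list
    planted_degs: dict                  # gene -> fold change applied in KO focal cells
    regulon_memberships: dict           # tf -> sorted target list
    scaling_factor: float
    focal_type: str
    eligible_types: list
    marker_genes: dict                  # cell type -> marker gene list
    seed: int
    params: dict = field(default_factory=dict)

    def regulons(self) -> list:
        return [Regulon(head_tf=t, targets=frozenset(g))
                for t, g in sorted(self.regulon_memberships.items())]


def _gene_catalog(sc: ScenarioConfig, types: list):
    """Names and structural roles for every gene, in a fixed order."""
    genes = []
    roles = {}
    mito = [f"mt-Nd{i+1}" for i in range(sc.n_mito_genes)]
    blood = [f"Hbb-b{i+1}" for i in range(sc.n_blood_genes)]
    tfs = [f"Tf{i:02d}" for i in range(sc.n_tfs)]
    markers = {t: [f"Mk-{t}-{j}" for j in range(sc.markers_per_type)] for t in types}
    targets = {tfs[i]: [f"Tg{i:02d}x{j:02d}" for j in range(sc.regulon_size)]
               for i in range(sc.n_tfs)}
    tier = [f"Hk{j:03d}" for j in range(sc.n_tier_genes)]
    buffer = [f"Bu{j:03d}" for j in range(sc.n_buffer_genes)]
    degs = [f"Deg{j:02d}" for j in range(sc.n_planted_degs)]
    fixed = mito + blood + ["Satb2"] + tfs
    for t in types:
        fixed += markers[t]
    for tf in tfs:
        fixed += targets[tf]
    fixed += tier + buffer + degs
    background = [f"Bg{j:04d}" for j in range(sc.n_genes - len(fixed))]
    genes = fixed + background
    roles = dict(mito=mito, blood=blood, tfs=tfs, markers=markers,
                 targets=targets, tier=tier, buffer=buffer, degs=degs, background=background)
    return genes, roles


def generate_dataset(scenario: ScenarioConfig | None = None, seed: int = 0):
    """Draw a full dataset; returns (CountMatrix, cell table, gene table, truth)."""
    sc = scenario or ScenarioConfig()
    rng = np.random.default_rng(seed)
    types = _CANONICAL_TYPES[: sc.n_cell_types]
    props = np.array(_TYPE_PROPS[: sc.n_cell_types])
    props = props / props.sum()
    eligible = [t for t in types if t in _ELIGIBLE]
    focal_type = "upper_layer"

    genes, roles = _gene_catalog(sc, types)
    g_index = pd.Index(genes)
    G = len(genes)
    tfs = roles["tfs"]

    # planted TF roles: partners first, decoys next (non-overlapping)
    partners = tfs[: sc.n_partner_tfs]
    decoys = tfs[sc.n_partner_tfs: sc.n_partner_tfs + sc.n_decoy_de_tfs]
    active_tfs = partners + decoys

    # TF families: a few bHLH among the non-planted TFs, rest cycled
    families = {}
    rest = [t for t in tfs if t not in active_tfs]
    for i, t in enumerate(tfs):
        families[t] = _FAMILIES[i % len(_FAMILIES)]
    for t in rest[:3]:
        families[t] = "bHLH"

    # per-type mean matrix (types x genes)
    tier_vals = sc.tier_median * np.exp(rng.normal(0.0, sc.tier_sigma, sc.n_tier_genes))
    type_mean = np.full((len(types), G), sc.background_mean)
    type_mean[:, g_index.get_indexer(roles["tier"])] = tier_vals[None, :]
    type_mean[:, g_index.get_indexer(roles["buffer"])] = sc.buffer_mean
    type_mean[:, g_index.get_indexer(roles["mito"])] = sc.mito_gene_mean
    type_mean[:, g_index.get_indexer(roles["blood"])] = 0.02
    type_mean[:, g_index.get_indexer(roles["degs"])] = sc.deg_base_mean
    for ti, t in enumerate(types):
        for tj, t2 in enumerate(types):
            cols = g_index.get_indexer(roles["markers"][t2])
            type_mean[ti, cols] = sc.marker_mean if t == t2 else sc.marker_off_mean
    satb2_col = g_index.get_loc("Satb2")
    satb2_by_type = {"upper_layer": 4.0, "newborn_neuron": 0.8,
                     "deep_layer": 0.5, "intermediate_progenitor": 0.5}
    for ti, t in enumerate(types):
        type_mean[ti, satb2_col] = satb2_by_type.get(t, 0.0)
    tf_cols = g_index.get_indexer(tfs)
    type_mean[:, tf_cols] = sc.tf_base_mean
    for ti, t in enumerate(types):
        for tf in tfs:
            cols = g_index.get_indexer(roles["targets"][tf])
            if tf in active_tfs and t in _ELIGIBLE:
                type_mean[ti, cols] = sc.active_target_mean
            else:
                type_mean[ti, cols] = sc.background_mean
        if t in _ELIGIBLE:
            type_mean[ti, g_index.get_indexer(active_tfs)] = sc.active_tf_mean

    deg_fold = {}
    for j, gname in enumerate(roles["degs"]):
        deg_fold[gname] = sc.deg_fold_change if j % 2 == 0 else 1.0 / sc.deg_fold_change

    # assemble cells sample by sample
    blocks = []
    cell_rows = []
    cell_counter = 0
    for geno in ["WT", "KO"]:
        for s in range(sc.n_samples):
            sample_id = f"{geno}{s+1}"
            n_c = sc.cells_per_sample + int(rng.integers(-sc.cell_jitter, sc.cell_jitter + 1))
            t_idx = rng.choice(len(types), size=n_c, p=props)
            lib = np.exp(rng.normal(0.0, sc.lib_sigma, n_c) - sc.lib_sigma**2 / 2)
            if geno == "KO":
                lib = lib * sc.ko_lib_factor
            lowq = rng.random(n_c) < sc.low_quality_fraction
            lowq_kind = rng.random(n_c) < 0.5  # True: tiny library, False: mito blowout
            contam = rng.random(n_c) < sc.contamination_fraction
            z = rng.standard_normal((sc.n_tfs, n_c))

            base = type_mean[t_idx]               # cells x genes, pre-noise means
            alpha = sc.dispersion_floor + (sc.dispersion - sc.dispersion_floor) * np.exp(
                -base / sc.dispersion_scale
            )
            mu = base.copy()
            mu *= lib[:, None]
            sig = sc.tf_latent_sigma
            beta = sc.target_coupling
            for i, tf in enumerate(tfs):
                if tf in active_tfs:
                    # program state: on/off per cell, genotype-independent
                    on = rng.random(n_c) < sc.program_on_prob
                    tf_fac = np.where(on, 1.0, sc.program_off_tf_factor)
                    tg_fac = np.where(on, 1.0, sc.program_off_target_factor)
                else:
                    tf_fac = np.exp(sig * z[i] - sig**2 / 2)
                    tg_fac = np.exp(beta * sig * z[i] - (beta * sig) ** 2 / 2)
                mu[:, tf_cols[i]] *= tf_fac
                mu[:, g_index.get_indexer(roles["targets"][tf])] *= tg_fac[:, None]

            in_eligible = np.isin(np.array(types)[t_idx], eligible)
            if geno == "KO":
                cells_pert = np.where(in_eligible)[0]
                if len(cells_pert):
                    for tf in partners:
                        cols = g_index.get_indexer(roles["targets"][tf])
                        mu[np.ix_(cells_pert, cols)] *= sc.partner_scaling
                    for tf in decoys:
                        cols = g_index.get_indexer(roles["targets"][tf])
                        mu[np.ix_(cells_pert, cols)] *= sc.partner_scaling
                        mu[cells_pert, g_index.get_loc(tf)] *= sc.decoy_expression_factor
                    for gname, fold in deg_fold.items():
                        mu[cells_pert, g_index.get_loc(gname)] *= fold

            # deliberate QC violations and blood contamination
            tiny = lowq & lowq_kind
            mu[tiny] *= 0.15
            mitoblow = lowq & ~lowq_kind
            mu[np.ix_(np.where(mitoblow)[0], g_index.get_indexer(roles["mito"]))] *= 5.0
            mu[np.ix_(np.where(contam)[0], g_index.get_indexer(roles["blood"]))] = (
                sc.contamination_blood_mean * lib[contam, None]
            )

            # negative binomial via gamma-Poisson, gene-wise dispersion
            lam = rng.gamma(1.0 / alpha, mu * alpha)
            counts = rng.poisson(lam).astype(np.int32)
            blocks.append(sp.csc_matrix(counts.T))  # genes x cells

            for j in range(n_c):
                cell_rows.append(
                    {
                        "cell_id": f"{sample_id}_c{cell_counter + j:04d}",
                        "sample_id": sample_id,
                        "genotype": geno,
                        "true_type": types[t_idx[j]],
                    }
                )
            cell_counter += n_c

    values = sp.hstack(blocks, format="csc")
    cell_ids = [r["cell_id"] for r in cell_rows]
    counts = CountMatrix(values=values, gene_ids=np.array(genes, dtype=object),
                         gene_symbols=np.array(genes, dtype=object),
                         cell_ids=np.array(cell_ids, dtype=object))

    cells = make_cell_table(cell_ids, [r["sample_id"] for r in cell_rows],
                            [r["genotype"] for r in cell_rows])
    cells["true_type"] = [r["true_type"] for r in cell_rows]

    is_tf = [g in set(tfs) for g in genes]
    func_sets = []
    neuro = set(active_tfs) | set(tfs[sc.n_partner_tfs + sc.n_decoy_de_tfs::2])
    for g in genes:
        func_sets.append({"neurogenesis"} if g in neuro else set())
    gene_table = make_gene_table(
        genes, genes,
        is_mito=[g in set(roles["mito"]) for g in genes],
        is_tf=is_tf,
        tf_family=[families.get(g, "") for g in genes],
        is_blood_marker=[g in set(roles["blood"]) for g in genes],
        functional_sets=func_sets,
    )

    truth = SyntheticTruth(
        planted_partner_tfs=list(partners),
        planted_de_tfs=list(decoys),
        planted_degs=deg_fold,
        regulon_memberships={tf: sorted(roles["targets"][tf]) for tf in tfs},
        scaling_factor=sc.partner_scaling,
        focal_type=focal_type,
        eligible_types=eligible,
        marker_genes={t: list(roles["markers"][t]) for t in types},
        seed=seed,
        params=asdict(sc),
    )
    return counts, cells, gene_table, truth


def write_fixture(dataset, out_dir) -> dict:
    """Write a generated dataset as a 10x-style triple plus annotation tables
    and a machine-readable truth file; round-trips through the readers."""
    counts, cells, gene_table, truth = dataset
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = rio.write_counts_mtx(counts, out)
    cells_out = cells.drop(columns=["focal"]).copy()
    cells_out.to_csv(out / "cells.tsv", sep="\t", index=False)
    gt = gene_table.copy()
    gt["functional_sets"] = gt["functional_sets"].map(lambda s: ";".join(sorted(s)))
    gt.to_csv(out / "genes.tsv", sep="\t", index=False)
    truth_dict = asdict(truth)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_dict, fh, indent=1, sort_keys=True)
    paths.update({"cells": str(out / "cells.tsv"), "genes": str(out / "genes.tsv"),
                  "truth": str(out / "truth.json")})
    return paths


def simulate_de_dataset(
    n_genes: int = 500,
    n_cells_per_genotype: int = 300,
    n_de: int = 0,
    fold_change: float = 2.0,
    dispersion: float = 0.5,
    ko_lib_factor: float = 0.7,
    base_mean_median: float = 0.5,
    base_mean_sigma: float = 0.8,
    lib_sigma: float = 0.3,
    seed: int = 0,
):
    """Small two-group NB dataset for DE calibration / power studies.

    The KO group's library sizes are shifted by ``ko_lib_factor`` so library
    depth is genotype-correlated (the confound the CDR covariate absorbs).
    The first ``n_de`` genes get ``fold_change`` applied in KO.  Returns
    (CountMatrix, cell table, list of perturbed gene ids).
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    base = base_mean_median * np.exp(rng.normal(0.0, base_mean_sigma, n_genes))
    de_genes = genes[:n_de]
    cells = []
    blocks = []
    for geno in ["WT", "KO"]:
        n_c = n_cells_per_genotype
        lib = np.exp(rng.normal(0.0, lib_sigma, n_c) - lib_sigma**2 / 2)
        if geno == "KO":
            lib = lib * ko_lib_factor
        mu = np.outer(lib, base)
        if geno == "KO" and n_de:
            mu[:, :n_de] *= fold_change
        lam = rng.gamma(1.0 / dispersion, mu * dispersion)
        counts = rng.poisson(lam).astype(np.int32)
        blocks.append(sp.csc_matrix(counts.T))
        cells += [{"cell_id": f"{geno}_c{i:04d}", "sample_id": geno, "genotype": geno}
                  for i in range(n_c)]
    values = sp.hstack(blocks, format="csc")
    cell_ids = [c["cell_id"] for c in cells]
    counts = CountMatrix(values=values, gene_ids=np.array(genes, dtype=object),
                         gene_symbols=np.array(genes, dtype=object),
                         cell_ids=np.array(cell_ids, dtype=object))
    table = make_cell_table(cell_ids, [c["sample_id"] for c in cells],
                            [c["genotype"] for c in cells])
    table["n_umis"] = counts.cell_totals()
    table["n_genes"] = counts.genes_per_cell()
    table["pct_mito"] = 0.0
    return counts, table, de_genes
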