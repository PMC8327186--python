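import logging

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from regdiscord.datatypes import CountMatrix, PipelineConfig, make_gene_table
from regdiscord.pipeline import run_pipeline
from regdiscord.simulate import ScenarioConfig, generate_dataset

logging.getLogger("regdiscord").setLevel(logging.WARNING)


@pytest.fixture
def tiny_counts():
    """3 genes x 2 cells with 4 nonzero entries, hand-written."""
    values = sp.csc_matrix(np.array([[5, 0], [1, 2], [0, 3]]))
    return CountMatrix(
        values=values,
        gene_ids=np.array(["gA", "gB", "gC"], dtype=object),
        gene_symbols=np.array(["A", "B", "C"], dtype=object),
        cell_ids=np.array(["c1", "c2"], dtype=object),
    )


@pytest.fixture
def default_config():
    return PipelineConfig(rng_seed=0)


def random_counts(n_genes=10, n_cells=5, seed=0, max_count=20):
    rng = np.random.default_rng(seed)
    vals = rng.integers(0, max_count, size=(n_genes, n_cells))
    vals[rng.random(vals.shape) < 0.5] = 0
    return CountMatrix(
        values=sp.csc_matrix(vals),
        gene_ids=np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        gene_symbols=np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        cell_ids=np.array([f"c{j}" for j in range(n_cells)], dtype=object),
    )


@pytest.fixture
def plain_gene_table():
    def _make(counts, mito=(), blood=(), tfs=()):
        return make_gene_table(
            counts.gene_ids,
            counts.gene_symbols,
            is_mito=[g in mito for g in counts.gene_ids],
            is_tf=[g in tfs for g in counts.gene_ids],
            is_blood_marker=[g in blood for g in counts.gene_ids],
        )

    return _make


@pytest.fixture(scope="session")
def default_dataset():
    """The default planted scenario, seed 1 (shared across the session)."""
    return generate_dataset(ScenarioConfig(), seed=1)


@pytest.fixture(scope="session")
def default_run(default_dataset, tmp_path_factory):
    """One full pipeline run on the default planted scenario, seed 1."""
    counts, cells, genes, truth = default_dataset
    cfg = PipelineConfig(rng_seed=1)
    out = tmp_path_factory.mktemp("default_run")
    res = run_pipeline(counts, cells, genes, cfg, truth.marker_genes, out)
    return res, truth, out


def small_scenario(**overrides):
    """A reduced scenario for fast pipeline-level tests."""
    base = dict(
        n_samples=2,
        cells_per_sample=420,
        cell_jitter=20,
        n_genes=1400,
        n_tfs=16,
        regulon_size=20,
        n_tier_genes=60,
        n_buffer_genes=90,
        n_planted_degs=20,
        markers_per_type=10,
    )
    base.update(overrides)
    return ScenarioConfig(**base)
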