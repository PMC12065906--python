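import numpy as np
import pandas as pd
import pytest

import smad4sig as s


def make_de(genes, log2fc, padj, contrast="c"):
    """Minimal DE result frame for rule tests."""
    genes = list(genes)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "base_mean": 100.0,
            "log2fc": np.asarray(log2fc, dtype=float),
            "se_log2fc": 0.1,
            "stat": 0.0,
            "pvalue": np.asarray(padj, dtype=float),
            "padj": np.asarray(padj, dtype=float),
            "contrast": contrast,
        }
    )


@pytest.fixture(scope="session")
def bulk_sim():
    """A medium planted-class simulation shared across read-only tests."""
    cfg = s.BulkSimConfig(n_genes=600, seed=11)
    cm, truth = s.simulate_bulk_counts(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def cohort_sim():
    cfg = s.CohortSimConfig(n_samples=300, seed=5)
    ct, truth = s.simulate_cohort(cfg)
    return cfg, ct, truth


@pytest.fixture(scope="session")
def cell_sim():
    cfg = s.CellSimConfig(n_cells_per_sample=800, seed=3)
    cells, truth = s.simulate_cells(cfg)
    return cfg, cells, truth
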