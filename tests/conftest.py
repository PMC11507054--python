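import logging

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from serrapath import CountDataset, SimConfig, generate_dataset, normalize

logging.getLogger("serrapath").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def null_dataset():
    """Two samples, no planted effects: the calibration workhorse."""
    cfg = SimConfig(
        n_samples_per_stage={"normal": 1, "SSL": 1},
        n_cells_per_sample=120,
        n_genes=800,
        n_continuum_genes=0,
        slope_range=(0.0, 0.0),
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def continuum_dataset():
    """Default 12-sample cohort with a planted continuum."""
    return generate_dataset(SimConfig(seed=3))


@pytest.fixture(scope="session")
def continuum_profile(continuum_dataset):
    from serrapath import profile_all_samples

    ds, truth = continuum_dataset
    norm = normalize(ds)
    return profile_all_samples(norm), ds, truth


def tiny_dataset(counts, stages=None, cell_types=None, gene_names=None, arms=None):
    """Hand-built CountDataset for arithmetic-level tests."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    stages = stages or ["normal"] * n_cells
    cell_types = cell_types or ["SLC1"] * n_cells
    gene_names = gene_names or [f"g{j}" for j in range(n_genes)]
    arms = arms or ["1p"] * n_genes
    cells = pd.DataFrame(
        {
            "barcode": [f"c{i}" for i in range(n_cells)],
            "sample_id": [f"s_{st}" for st in stages],
            "stage": stages,
            "cell_type": cell_types,
        }
    )
    genes = pd.DataFrame(
        {
            "gene_id": gene_names,
            "gene_name": gene_names,
            "chromosome": [a.rstrip("pq") for a in arms],
            "start": np.arange(n_genes) * 1000 + 1,
            "end": np.arange(n_genes) * 1000 + 500,
            "arm": arms,
        }
    )
    return CountDataset(counts=sp.csr_matrix(counts), cells=cells, genes=genes)
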