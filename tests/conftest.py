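import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from atlaskit import simulate
from atlaskit.data import CellDataset


def make_dataset(counts, patients, cell_types, datasets=None, tissues=None,
                 genes=None, cells=None):
    """Hand-build a CellDataset from a dense count array and metadata lists."""
    counts = np.asarray(counts)
    n, g = counts.shape
    cells = pd.Index(cells or [f"c{i}" for i in range(n)])
    genes = pd.Index(genes or [f"g{j}" for j in range(g)])
    datasets = datasets or ["ds0"] * n
    meta = pd.DataFrame(
        {
            "patient": patients,
            "sample": [f"{p}_s1" for p in patients],
            "dataset": datasets,
            "cell_type": cell_types,
            "tissue": tissues or ["tumor_primary"] * n,
        },
        index=cells,
    )
    return CellDataset(counts=sp.csr_matrix(counts), genes=genes, cells=cells,
                       cell_meta=meta)


@pytest.fixture
def tiny_dataset():
    """6 cells, 4 genes, 2 patients, 2 cell types."""
    counts = np.array([
        [5, 0, 1, 2],
        [4, 1, 0, 3],
        [0, 6, 2, 1],
        [1, 5, 3, 0],
        [2, 2, 2, 2],
        [3, 3, 0, 1],
    ])
    return make_dataset(
        counts,
        patients=["p1", "p1", "p1", "p2", "p2", "p2"],
        cell_types=["T", "T", "B", "B", "T", "B"],
    )


@pytest.fixture(scope="session")
def marker_atlas():
    """Small simulated atlas with planted markers, shared across tests."""
    cfg = simulate.default_atlas_config(
        n_genes=500, n_cell_types=3, n_datasets=2, patients_per_dataset=6,
        markers_per_type=20, marker_log2_effect=2.0,
        cells_per_patient_per_type=(20, 60), seed=42,
    )
    return simulate.generate_atlas(cfg)
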