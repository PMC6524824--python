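import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from scapa import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with planted signatures, shared across tests."""
    config = SimConfig(
        n_cell_types=3, cells_per_type=20, n_patients=4,
        n_genes=300, n_gene_sets=40, genes_per_set=(8, 12),
        planted_sets_per_type=2, seed=7,
    )
    return simulate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_score_frame(rng, n_genes=20, n_cells=5, missing=0.0):
    vals = rng.normal(size=(n_genes, n_cells))
    if missing:
        vals[rng.random(vals.shape) < missing] = np.nan
    return pd.DataFrame(
        vals,
        index=[f"g{i:03d}" for i in range(n_genes)],
        columns=[f"c{i}" for i in range(n_cells)],
    )
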