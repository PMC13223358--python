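"""Shared fixtures: a small synthetic tissue used across the suite."""

import numpy as np
import pytest

from txseg.preprocess import compute_noise_distance_scores, encode_genes
from txseg.synthetic import SyntheticTissueSpec, simulate_dataset


@pytest.fixture(scope="session")
def tiny_spec():
    return SyntheticTissueSpec(
        n_cells=30, n_types=4, n_genes=40, mean_transcripts=80.0,
        ref_cells_per_type=25, ref_library_size=500, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_data(tiny_spec):
    """Encoded (table, panel, truth) for a 30-cell tissue (~1.3k molecules)."""
    table, panel, truth = simulate_dataset(tiny_spec)
    table, panel = encode_genes(
        table.to_frame(), (panel.U, panel.all_genes, panel.cell_type)
    )
    compute_noise_distance_scores(table)
    return table, panel, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
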