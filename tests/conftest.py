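import warnings

import numpy as np
import pytest

import scquery as sq


@pytest.fixture(scope="session")
def sim_single_batch():
    """900-cell, 3-cluster, single-batch NB dataset with informative genes."""
    design = sq.SimulationDesign(n_cells=900, n_genes=200, n_clusters=3,
                                 n_batches=1, sigma_batch=0.0, seed=2)
    matrix, truth = sq.simulate_dataset(design)
    matrix.selected_genes = sq.select_variable_genes(matrix)
    return matrix, truth


@pytest.fixture(scope="session")
def small_config():
    return sq.ModelConfig(latent_dim=8, n_components=6, hidden_dim=32,
                          epochs=50, seed=0)


@pytest.fixture(scope="session")
def trained_model(sim_single_batch, small_config):
    matrix, _ = sim_single_batch
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return sq.fit(matrix, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
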