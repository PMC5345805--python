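import numpy as np
import pandas as pd
import pytest

from crabtree.synthetic import (
    FermentationParams,
    SyntheticDEConfig,
    simulate_batch_fermentation,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def de_table():
    """Small hand-written DE table covering all calling regimes."""
    return pd.DataFrame({
        "gene_id": ["g1", "g2", "g3", "g4", "g5", "g6"],
        "fold_change": [1.6, -1.6, 1.6, 1.2, 2.5, -1.01],
        "p_value": [1e-4, 1e-4, 0.9, 1e-5, 1e-4, 0.5],
    })


@pytest.fixture(scope="session")
def ferm_result():
    """Reference fermentation: mu 0.25/h, ethanol yield 0.35 g/g, 3 h lag."""
    params = FermentationParams.with_ethanol_yield(
        0.35, mu_glc=0.25, diauxic_lag=3.0)
    return simulate_batch_fermentation(params)


@pytest.fixture(scope="session")
def coculture_result():
    params = FermentationParams.with_ethanol_yield(0.35)
    return simulate_batch_fermentation(params, co_culture=True)


@pytest.fixture(scope="session")
def small_de_config():
    return SyntheticDEConfig(n_genes=2000, n_pathways=40,
                             background_misregulated=500, seed=3)
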