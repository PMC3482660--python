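import numpy as np
import pandas as pd
import pytest

from absquant.simulate import (
    SimulationConfig,
    generate_catalog,
    generate_truth,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_catalog(default_config):
    return generate_catalog(default_config)


@pytest.fixture(scope="session")
def default_truth(default_config, default_catalog):
    return generate_truth(default_catalog, default_config)


@pytest.fixture()
def small_config() -> SimulationConfig:
    """Scaled-down study for fast per-test simulation."""
    return SimulationConfig(
        seed=7,
        n_mrna=300,
        n_lncrna=80,
        n_anchors=30,
        n_protein_anchors=25,
        depth=500_000.0,
        n_cells=60,
    )


def expression_from_series(condition: str, copies: pd.Series):
    from absquant.core import ExpressionTable

    return ExpressionTable.from_copies(condition, copies)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
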