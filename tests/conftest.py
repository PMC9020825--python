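import numpy as np
import pandas as pd
import pytest

from drivereg import SimConfig, build_benchmark_dataset


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale benchmark: same structure as the default, fewer cells/genes."""
    return SimConfig(n_cells=600, n_genes=400, n_drivers=60, n_regulons=4,
                     targets_per_regulon=8)


@pytest.fixture(scope="session")
def small_benchmark(small_config):
    return build_benchmark_dataset(small_config, seed=7)


@pytest.fixture(scope="session")
def default_benchmark():
    """One full-size benchmark realisation, shared across tests."""
    return build_benchmark_dataset(seed=11)


@pytest.fixture()
def toy_expr():
    """Tiny deterministic expression table for hand-checked computations."""
    return pd.DataFrame(
        [[4.0, 0.0, 1.0, 0.0],
         [0.0, 3.0, 0.0, 2.0],
         [2.0, 2.0, 1.0, 1.0],
         [0.0, 0.0, 0.0, 0.0]],
        index=["c1", "c2", "c3", "c4"],
        columns=["gA", "gB", "gC", "gD"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
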