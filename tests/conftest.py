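import numpy as np
import pytest

import dielscan as ds


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic study shared across read-only tests."""
    cfg = ds.SimulationConfig(n_pangenes=40, n_snps=800,
                              n_individuals=60, seed=1)
    return ds.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_rhythm(small_dataset):
    return ds.rhythm_scan(small_dataset.field_expression)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def field_times():
    return np.arange(6.0, 30.0, 2.0)
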