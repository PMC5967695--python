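import numpy as np
import pytest

import lapnuts as ln


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def std_normal_1d():
    return ln.mvn_model([0.0], [[1.0]])


@pytest.fixture(scope="session")
def small_wildflower():
    data = ln.gen_wildflower(n_plants=8, n_years=3, seed=11)
    return ln.wildflower_model(data)


@pytest.fixture(scope="session")
def small_fit(std_normal_1d):
    """A small but real NUTS fit reused by extraction/diagnostic tests."""
    return ln.sample(std_normal_1d, chains=3, iter=400, warmup=200, seed=5)
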