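import numpy as np
import pytest

from morphovar import SyntheticConfig, generate_grouped_shapes


@pytest.fixture(scope="session")
def island_data():
    """Seven groups of 40, p = 14, anisotropy 10, shared Pmax, means
    displaced dominantly along it — the study-like synthetic conditions."""
    cfg = SyntheticConfig(n_per_group=(40,) * 7, seed=0)
    return generate_grouped_shapes(cfg)


@pytest.fixture(scope="session")
def default_data():
    """Generator defaults: the study's seven continental sample sizes."""
    return generate_grouped_shapes(SyntheticConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
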