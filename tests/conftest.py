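import numpy as np
import pytest

from hpct.synthetic import SyntheticConfig, gen_embeddings


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale generator settings shared across tests: 64 channels,
    rank-4 signal, three outlier channels, mild noise."""
    return SyntheticConfig(
        n_samples=16,
        length_range=(8, 20),
        n_channels=64,
        intrinsic_rank=4,
        outlier_channels=(7, 33, 2),
        outlier_scale=1000.0,
        noise_sd=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return gen_embeddings(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
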