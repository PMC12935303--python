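import numpy as np
import pytest

import featuredca as fd


@pytest.fixture(scope="session")
def tiny_model():
    """Enumerable conditioned model (L=4, q=3, d=2)."""
    return fd.make_tiny_model(4, 3, 2, scale=0.7, seed=3)


@pytest.fixture(scope="session")
def tiny_model_d0():
    """Enumerable unconditioned model (L=4, q=3, d=0)."""
    return fd.make_tiny_model(4, 3, 0, scale=0.7, seed=4)


@pytest.fixture(scope="session")
def two_cluster_msa():
    """Small two-cluster alignment with coupled pairs (M=400, L=20, q=6)."""
    spec = fd.ClusterSpec(
        cluster_sizes=(200, 200), L=20, q=6,
        profile_divergence=0.8, coupled_pair_fraction=0.2, seed=21,
    )
    return fd.make_cluster_msa(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
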