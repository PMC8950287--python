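import numpy as np
import pytest

from pollinet import BipartiteNetwork, fixture_network, network_from_matrix


@pytest.fixture(scope="session")
def fixture_net() -> BipartiteNetwork:
    """Reconstructed survey network (printed degree sequences, 42 links)."""
    return fixture_network()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_network(rng, max_r=6, max_a=6, weighted=False) -> BipartiteNetwork:
    """Random valid network used by property tests."""
    while True:
        r = rng.integers(2, max_r + 1)
        a = rng.integers(2, max_a + 1)
        density = rng.uniform(0.3, 0.9)
        m = (rng.random((r, a)) < density).astype(int)
        if weighted:
            m = m * rng.integers(1, 9, size=(r, a))
        if m.sum(axis=1).all() and m.sum(axis=0).all():
            return network_from_matrix(m)
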