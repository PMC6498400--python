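import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_recording():
    """Factory for small random raw recordings (channels x samples)."""

    def make(n_channels=3, n_samples=10, seed=0):
        r = np.random.default_rng(seed)
        return r.uniform(size=(n_channels, n_samples))

    return make


def random_graph_edges(n_nodes, n_edges, rng):
    """Uniform-random simple graph as an edge list."""
    pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    idx = rng.choice(len(pairs), size=n_edges, replace=False)
    return [pairs[k] for k in idx]
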