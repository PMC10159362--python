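import numpy as np
import pytest

from multicens import MultilayerNetwork


def make_random_network(
    n: int,
    L: int,
    seed: int,
    density: float = 0.3,
    isolate: int = 0,
) -> MultilayerNetwork:
    """Random symmetric weighted multilayer network; optionally isolate nodes."""
    rng = np.random.default_rng(seed)
    N = n * L
    W = rng.random((N, N)) * (rng.random((N, N)) < density)
    M = np.triu(W, 1)
    M = M + M.T
    for i in range(isolate):
        M[i, :] = 0.0
        M[:, i] = 0.0
    layers = [f"L{a}" for a in range(L)]
    nodes = [f"n{i:03d}" for i in range(n)]
    return MultilayerNetwork(layers, nodes, M)


@pytest.fixture
def small_net() -> MultilayerNetwork:
    return make_random_network(n=8, L=2, seed=42)


@pytest.fixture
def edgeless_net() -> MultilayerNetwork:
    return MultilayerNetwork(["L0", "L1"], ["n0", "n1", "n2"], np.zeros((6, 6)))
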