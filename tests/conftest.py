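import numpy as np
import pytest

import heatlink as hl


@pytest.fixture
def two_node_graph():
    """Single edge of weight 0.5; the heat matrix is [[-1, 1], [1, -1]]."""
    return hl.SimilarityGraph(["a", "b"], {(0, 1): 0.5})


@pytest.fixture
def toy():
    """Fixed 3 side-effect x 6 drug fixture with a connected similarity graph."""
    return hl.make_toy_fig2()


@pytest.fixture
def small_dataset():
    """Planted-factor dataset small enough for exact-kernel cross-checks."""
    return hl.generate(hl.SyntheticSpec(m=30, n=20, r_true=3,
                                        link_density=0.15, seed=7))


def random_similarity_graph(n, p, seed, weight_scale=1.0):
    """Erdos-Renyi-style weighted graph used across diffusion tests."""
    rng = np.random.default_rng(seed)
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(i, j)] = float(rng.uniform(0.05, 1.0) * weight_scale)
    return hl.SimilarityGraph([f"n{k}" for k in range(n)], edges)
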