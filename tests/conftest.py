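import logging

import numpy as np
import pytest

from antnets import ColonyNetwork, ModelParams

logging.getLogger("antnets").setLevel(logging.ERROR)


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_net() -> ColonyNetwork:
    """Two nests and one tree, one internest and two foraging trails.

    Layout: nest A (0, 0, size 100) - nest B (4, 0, size 50), tree T at
    (0, 3).  Trails: A-B (internest, 4 m), A-T (foraging, 3 m)."""
    net = ColonyNetwork(60.0)
    a = net.add_nest(0.0, 0.0, 100.0)
    b = net.add_nest(4.0, 0.0, 50.0)
    t = net.add_tree(0.0, 3.0)
    net.add_trail(a, b, strength=1.0)
    net.add_trail(a, t, strength=2.0)
    net._ids = (a, b, t)
    return net


def random_spatial_graph(rng, n_nodes=None, p_edge=0.6):
    """Random weighted graph fixture for measure-oracle comparisons."""
    from antnets.measures import SpatialGraph

    n = int(n_nodes if n_nodes is not None else rng.integers(2, 7))
    nodes = list(range(n))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                edges.append((i, j, float(rng.uniform(0.5, 10.0))))
    return SpatialGraph(nodes, edges)
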