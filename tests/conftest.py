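import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

from gec import Network

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture
def fig1_net() -> Network:
    """The 4-node fragment a-b, b-c, b-e used in the worked example."""
    return Network(edges=[("a", "b"), ("b", "c"), ("b", "e")])


@pytest.fixture
def path3() -> Network:
    return Network(edges=[("a", "b"), ("b", "c")])


@pytest.fixture
def claw() -> Network:
    """Star K(1,3): hub h with leaves x, y, z."""
    return Network(edges=[("h", "x"), ("h", "y"), ("h", "z")])


@pytest.fixture
def triangle() -> Network:
    return Network(edges=[("x", "y"), ("y", "z"), ("x", "z")])


@pytest.fixture
def k4() -> Network:
    nodes = "abcd"
    return Network(edges=[(u, v) for i, u in enumerate(nodes)
                          for v in nodes[i + 1:]])


@pytest.fixture
def triangle_plus_edge() -> Network:
    """Triangle {x,y,z} plus the separate edge {p,q}."""
    return Network(
        edges=[("x", "y"), ("y", "z"), ("x", "z"), ("p", "q")]
    )


def random_network(n: int, p: float, seed: int) -> Network:
    return Network.from_networkx(nx.gnp_random_graph(n, p, seed=seed))


@pytest.fixture
def dense_net() -> Network:
    """An ER instance dense enough that all nine graphlet supports are
    non-empty and connected (verified in the spectral tests)."""
    return random_network(30, 0.3, seed=3)


@pytest.fixture
def small_random_nets() -> list[Network]:
    rng = np.random.default_rng(11)
    nets = []
    for _ in range(8):
        n = int(rng.integers(6, 13))
        p = float(rng.uniform(0.2, 0.5))
        nets.append(random_network(n, p, int(rng.integers(1 << 30))))
    return nets
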