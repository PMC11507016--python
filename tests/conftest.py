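import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dupdiv import WeightedGraph, build_graph, make_fixture  # noqa: E402
from oracles import random_weighted_graph  # noqa: E402


@pytest.fixture
def triangle() -> WeightedGraph:
    return make_fixture("triangle")


@pytest.fixture
def star5() -> WeightedGraph:
    return make_fixture("star5")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240813)


@pytest.fixture
def random_graphs(rng):
    """A batch of small random weighted graphs as WeightedGraph instances."""

    def batch(count, max_nodes=8, unit_weights=False):
        out = []
        for _ in range(count):
            nodes, edges = random_weighted_graph(rng, max_nodes, unit_weights)
            out.append((build_graph(nodes, edges), nodes, edges))
        return out

    return batch
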