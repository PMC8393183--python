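import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=30)
settings.load_profile("ci")


@pytest.fixture
def two_cliques() -> nx.Graph:
    """Two disjoint 5-cliques: the canonical Q = 0.5 fixture."""
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
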