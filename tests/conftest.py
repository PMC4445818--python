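import random

import networkx as nx
import pytest

from ppitopo import fig1_network


@pytest.fixture
def fig1():
    return fig1_network()


def random_graph(seed: int, max_nodes: int = 12) -> nx.Graph:
    """Random graph with string node labels, <= max_nodes nodes, varied
    density; deterministic per seed."""
    rng = random.Random(seed)
    n = rng.randint(1, max_nodes)
    p = rng.uniform(0.05, 0.7)
    g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1))
    return nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes()})


def thresholded_graph(g: nx.Graph, t: int) -> nx.Graph:
    """Graph on the same nodes with an edge wherever hop distance <= t;
    its flag complex is the Rips complex K^t."""
    h = nx.Graph()
    h.add_nodes_from(g.nodes())
    if t >= 1:
        lengths = dict(nx.all_pairs_shortest_path_length(g, cutoff=t))
        for u, dd in lengths.items():
            for v, d in dd.items():
                if u != v and d <= t:
                    h.add_edge(u, v)
    return h
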