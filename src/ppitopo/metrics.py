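"""Classical network-complexity statistics: degree-entropy, betweenness
centrality and the GF(2) cycle basis.

These are the companion statistics reported next to the homology-based
complexity score: degree-entropy summarises the degree distribution,
betweenness ranks nodes that carry shortest-path traffic (used to break ties
between knockout targets of equal effect), and the cycle-basis dimension
|E| - |V| + #components counts all independent cycles of length >= 3.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .network import PPINetwork

__all__ = [
    "CycleBasis",
    "degree_distribution",
    "degree_entropy",
    "betweenness_centrality",
    "cycle_basis",
]


def degree_distribution(net: PPINetwork) -> dict[int, float]:
    """Empirical degree distribution p(k) = N_k / N."""
    if net.number_of_nodes() == 0:
        raise ValueError("degree distribution of an empty network is undefined")
    n = net.number_of_nodes()
    counts = Counter(d for _, d in net.degree())
    return {k: nk / n for k, nk in sorted(counts.items())}


def degree_entropy(net: PPINetwork) -> float:
    """Shannon entropy H = -sum_k p(k) ln p(k) of the degree distribution.

    Natural logarithm, units of nats.  H = 0 exactly when every node has the
    same degree (e.g. any k-regular graph).
    """
    return -sum(p * math.log(p) for p in degree_distribution(net).values())


def betweenness_centrality(net: PPINetwork) -> dict[str, float]:
    """Unnormalised betweenness centrality c_B(v).

    c_B(v) sums, over unordered node pairs {s, t} with s != v != t, the
    fraction sigma(s,t|v)/sigma(s,t) of shortest s-t paths passing through
    v.  Pairs in different components contribute 0.  Only the relative
    ordering is used downstream (knockout tie-breaking), so no
    normalisation constant is applied.
    """
    return nx.betweenness_centrality(net, normalized=False)


@dataclass(frozen=True)
class CycleBasis:
    """A basis of the GF(2) cycle space of a graph.

    ``cycles`` holds one frozenset of (sorted-pair) edges per basis element;
    ``dimension`` equals |E| - |V| + #components, the rank of the cycle
    space.
    """

    cycles: tuple[frozenset[tuple[str, str]], ...]
    dimension: int

    def __len__(self) -> int:
        return self.dimension


def _cycle_edges(node_cycle: list[str]) -> frozenset[tuple[str, str]]:
    pairs = zip(node_cycle, node_cycle[1:] + node_cycle[:1])
    return frozenset(tuple(sorted(p)) for p in pairs)


def cycle_basis(net: PPINetwork) -> CycleBasis:
    """Cycle basis via spanning-tree fundamental cycles (Paton's method).

    Any valid basis spans the same GF(2) cycle space; only the dimension is
    compared across networks.  The dimension is checked against the closed
    form |E| - |V| + #components.
    """
    node_cycles = nx.cycle_basis(net)
    cycles = tuple(_cycle_edges(c) for c in node_cycles)
    dim = (
        net.number_of_edges()
        - net.number_of_nodes()
        + nx.number_connected_components(net)
    )
    if len(cycles) != dim:
        raise AssertionError(
            f"cycle basis size {len(cycles)} != |E|-|V|+c = {dim}"
        )
    return CycleBasis(cycles=cycles, dimension=dim)
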