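"""Reading, writing and generating protein-protein interaction networks.

A PPI network is represented as an undirected simple :class:`networkx.Graph`
whose nodes are opaque gene-symbol strings.  All readers canonicalise their
input the same way: directed or annotated edges are symmetrised, duplicate
edges are merged and self-loops are dropped with a warning (self-loops carry
no cycle-space or hop-metric information, and curated pathway exports may
contain them).  Node identifiers are case-sensitive and are never normalised.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "SyntheticSpec",
    "ParseError",
    "read_edge_list",
    "read_adjacency_list",
    "write_edge_list",
    "write_adjacency_list",
    "fig1_network",
    "generate_synthetic",
]

#: In-memory container for PPI networks: an undirected simple graph with
#: string node identifiers.
PPINetwork = nx.Graph


class ParseError(ValueError):
    """Raised when a network file line cannot be interpreted."""


def _new_network() -> PPINetwork:
    return nx.Graph()


def _add_edge(net: PPINetwork, u: str, v: str, *, where: str) -> None:
    if u == v:
        logger.warning("%s: dropping self-loop on node %r", where, u)
        net.add_node(u)
        return
    net.add_edge(u, v)


def read_edge_list(
    path,
    delimiter: str | None = None,
    *,
    sif: bool = False,
) -> PPINetwork:
    """Read an undirected network from a two-column edge list.

    Parameters
    ----------
    path : str or Path
        Text file with one edge per line, ``#`` comments allowed.
    delimiter : str, optional
        Field delimiter; default splits on any whitespace (covers both
        space- and tab-separated files).
    sif : bool
        Accept the SIF dialect ``node relation node`` by skipping the
        middle column on three-field lines.

    Returns
    -------
    networkx.Graph
        Simple undirected graph; duplicate edges merged, self-loops dropped.
    """
    net = _new_network()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}: {line!r}"
                )
            if sif and len(fields) >= 3:
                u, v = fields[0], fields[2]
            else:
                u, v = fields[0], fields[1]
            _add_edge(net, u, v, where=f"{path}:{lineno}")
    return net


def read_adjacency_list(path, delimiter: str | None = None) -> PPINetwork:
    """Read a network from an adjacency list (node followed by neighbours).

    Lines look like ``A<TAB>B<TAB>C`` or ``A: B C``; a trailing colon on the
    first field is tolerated.  The symmetric closure is taken: an edge is
    present if it is listed on either endpoint's line.
    """
    net = _new_network()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if not fields:
                continue
            node = fields[0].rstrip(":")
            if not node:
                raise ParseError(f"{path}:{lineno}: empty node identifier")
            net.add_node(node)
            for nb in fields[1:]:
                _add_edge(net, node, nb, where=f"{path}:{lineno}")
    return net


def write_edge_list(net: PPINetwork, path, delimiter: str = "\t") -> None:
    """Write a network as a sorted two-column edge list.

    Isolated nodes cannot be expressed in this format and are silently
    omitted; use :func:`write_adjacency_list` to round-trip them.
    """
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}{delimiter}{v}\n")


def write_adjacency_list(net: PPINetwork, path, delimiter: str = "\t") -> None:
    """Write a network as an adjacency list; round-trips isolated nodes."""
    with open(path, "w") as fh:
        for node in sorted(net.nodes()):
            nbrs = sorted(net.neighbors(node))
            fh.write(delimiter.join([node, *nbrs]) + "\n")


#: The 11 edges of the worked 9-node example: two 4-cycles joined by a triangle.
_FIG1_EDGES = [
    ("1", "2"), ("2", "3"), ("3", "4"), ("4", "1"),
    ("5", "6"), ("6", "7"), ("7", "8"), ("8", "5"),
    ("1", "5"), ("5", "9"), ("9", "1"),
]


def fig1_network() -> PPINetwork:
    """The bundled 9-node reference network: two cycles of length 4
    (1-2-3-4 and 5-6-7-8) connected through the triangle 1-5-9."""
    net = _new_network()
    net.add_edges_from(_FIG1_EDGES)
    return net


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification for a planted-cycle synthetic network.

    The generator plants vertex-disjoint cycles of the given lengths and
    joins all pieces into one connected component with tree bridges, so the
    number of independent cycles (of any length) is exactly
    ``len(cycle_lengths)`` and the expected one-dimensional homology at
    filtration index 1 is the number of planted cycles of length >= 4
    (triangles bound immediately and contribute nothing).
    """

    cycle_lengths: Sequence[int] = field(default_factory=lambda: (4, 4, 5))
    n_bridge_nodes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cycle_lengths:
            raise ValueError("cycle_lengths must be non-empty")
        bad = [L for L in self.cycle_lengths if int(L) < 3]
        if bad:
            raise ValueError(f"cycle lengths must be >= 3, got {bad}")
        if self.n_bridge_nodes < 0:
            raise ValueError("n_bridge_nodes must be non-negative")


def generate_synthetic(spec: SyntheticSpec) -> PPINetwork:
    """Generate a connected network with planted vertex-disjoint cycles.

    Deterministic for a fixed ``spec.seed``.  The returned graph carries
    metadata in ``G.graph``: ``expected_betti`` (number of planted cycles of
    length >= 4, the analytic value of the index-1 one-dimensional Betti
    number) and ``planted_cycles`` (the node tuples of each cycle).
    """
    rng = random.Random(spec.seed)
    net = _new_network()
    cycles: list[tuple[str, ...]] = []
    for ci, length in enumerate(spec.cycle_lengths):
        nodes = tuple(f"c{ci}n{j}" for j in range(int(length)))
        for a, b in zip(nodes, nodes[1:] + nodes[:1]):
            net.add_edge(a, b)
        cycles.append(nodes)

    # components to be joined by tree bridges: the cycles plus each bridge node
    components: list[list[str]] = [list(c) for c in cycles]
    for bi in range(spec.n_bridge_nodes):
        node = f"b{bi}"
        net.add_node(node)
        components.append([node])
    rng.shuffle(components)

    # attach each component to one node already placed: a tree of components,
    # so no new cycle is created
    placed = list(components[0])
    for comp in components[1:]:
        net.add_edge(rng.choice(comp), rng.choice(placed))
        placed.extend(comp)

    net.graph["expected_betti"] = sum(1 for c in cycles if len(c) >= 4)
    net.graph["planted_cycles"] = tuple(cycles)
    return net
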