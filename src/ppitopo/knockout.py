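"""In-silico node knockouts: the computational surrogate of protein
inhibition.

Removing a protein from a PPI network (the node and all incident edges)
can only destroy or preserve independent cycles, so the complexity score
β_1^{1,1} never increases under removal of nodes on vertex-disjoint cycles.
The scans below remove every single node, and every unordered node pair,
recompute the score on the residual graph, and rank the removals: targets
whose removal attains the same score form an equivalence class, and ties
are broken by the betweenness centrality of the removed node (the maximum
over the pair for double knockouts) — nodes bridging sub-networks rank
first.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import networkx as nx

from .homology import DEFAULT_T_MAX, nominal_betti, build_rips, persistent_homology, persistent_betti
from .metrics import betweenness_centrality
from .network import PPINetwork

__all__ = [
    "KnockoutResult",
    "TargetReport",
    "knockout",
    "single_scan",
    "double_scan",
    "components_after",
]


@dataclass(frozen=True)
class KnockoutResult:
    """Outcome of removing one or two nodes from a network."""

    removed: frozenset[str]
    betti_after: int
    delta: int
    components_after: int


@dataclass(frozen=True)
class TargetReport:
    """Ranked knockout scan over a network.

    ``ranked`` is ordered by (betti_after ascending, betweenness of the
    removed set descending); ``equivalence_classes`` groups removed-sets by
    identical betti_after, keyed by that value in ascending order.
    """

    nominal: int
    best_betti: int
    results: tuple[KnockoutResult, ...]
    ranked: tuple[KnockoutResult, ...]
    equivalence_classes: dict[int, tuple[frozenset[str], ...]]

    @property
    def best_targets(self) -> tuple[frozenset[str], ...]:
        """All removed-sets attaining the best (lowest) score."""
        return self.equivalence_classes[self.best_betti]


def _check_nodes(net: PPINetwork, nodes: Iterable[str]) -> frozenset[str]:
    ns = frozenset(nodes)
    unknown = [n for n in ns if n not in net]
    if unknown:
        raise KeyError(f"node(s) not in network: {sorted(unknown)}")
    if not 1 <= len(ns) <= 2:
        raise ValueError(f"knockouts remove 1 or 2 nodes, got {len(ns)}")
    return ns


def _residual(net: PPINetwork, ns: frozenset[str]) -> PPINetwork:
    res = net.copy()
    res.remove_nodes_from(ns)
    return res


def knockout(
    net: PPINetwork,
    nodes: Iterable[str],
    *,
    nominal: int | None = None,
    t_max: int = DEFAULT_T_MAX,
) -> KnockoutResult:
    """Remove ``nodes`` (and incident edges) and recompute the complexity
    score and component count on the residual graph.

    The input network is left unmodified.  ``nominal`` (the intact score)
    may be passed to avoid recomputation during scans.
    """
    ns = _check_nodes(net, nodes)
    if nominal is None:
        nominal = nominal_betti(net, t_max=t_max)
    res = _residual(net, ns)
    betti_after = nominal_betti(res, t_max=t_max)
    return KnockoutResult(
        removed=ns,
        betti_after=betti_after,
        delta=nominal - betti_after,
        components_after=nx.number_connected_components(res),
    )


def components_after(net: PPINetwork, nodes: Iterable[str]) -> int:
    """Number of connected components of the residual graph.

    Computed as β_0^{0,1} of the residual graph's Rips filtration and
    cross-checked against direct graph traversal.
    """
    ns = _check_nodes(net, nodes)
    res = _residual(net, ns)
    if res.number_of_nodes() == 0:
        return 0
    barcode = persistent_homology(build_rips(res, t_max=1, max_dim=1))
    via_homology = persistent_betti(barcode, 0, 0, 1)
    via_traversal = nx.number_connected_components(res)
    if via_homology != via_traversal:
        raise AssertionError(
            f"component count mismatch: homology {via_homology} vs traversal {via_traversal}"
        )
    return via_homology


def _build_report(
    net: PPINetwork,
    nominal: int,
    results: list[KnockoutResult],
) -> TargetReport:
    cb = betweenness_centrality(net)

    def tie_break(r: KnockoutResult) -> float:
        return max(cb[n] for n in r.removed)

    ranked = tuple(
        sorted(results, key=lambda r: (r.betti_after, -tie_break(r), sorted(r.removed)))
    )
    classes: dict[int, list[frozenset[str]]] = {}
    for r in ranked:
        classes.setdefault(r.betti_after, []).append(r.removed)
    return TargetReport(
        nominal=nominal,
        best_betti=min(r.betti_after for r in results),
        results=tuple(results),
        ranked=ranked,
        equivalence_classes={k: tuple(v) for k, v in sorted(classes.items())},
    )


def single_scan(net: PPINetwork, *, t_max: int = DEFAULT_T_MAX) -> TargetReport:
    """Knock out every node in turn and rank the targets."""
    if net.number_of_nodes() == 0:
        raise ValueError("cannot scan an empty network")
    nominal = nominal_betti(net, t_max=t_max)
    results = [
        knockout(net, {n}, nominal=nominal, t_max=t_max) for n in sorted(net.nodes())
    ]
    return _build_report(net, nominal, results)


def double_scan(
    net: PPINetwork,
    candidate_limit: int | None = None,
    *,
    t_max: int = DEFAULT_T_MAX,
) -> TargetReport:
    """Knock out every unordered node pair and rank the pairs.

    With ``candidate_limit`` set, pairs are drawn only from the top-ranked
    nodes of a preliminary single scan — an optimisation for large
    networks; by default the full O(n^2) scan is run.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("double scan needs at least 2 nodes")
    nominal = nominal_betti(net, t_max=t_max)
    if candidate_limit is not None:
        singles = single_scan(net, t_max=t_max)
        pool = sorted(
            {next(iter(r.removed)) for r in singles.ranked[:candidate_limit]}
        )
    else:
        pool = sorted(net.nodes())
    results = [
        knockout(net, {u, v}, nominal=nominal, t_max=t_max)
        for u, v in combinations(pool, 2)
    ]
    return _build_report(net, nominal, results)
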