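"""Persistent homology of a network over the hop metric.

The pipeline is the classical one for topological analysis of graphs:

1. endow the node set with the shortest-path (hop) metric, every edge having
   length 1;
2. build the Vietoris-Rips (flag) filtration ``K^0 ⊂ K^1 ⊂ … ⊂ K^t_max``:
   an edge {v, w} enters at index d(v, w), and a triangle enters as soon as
   all three of its edges are present;
3. reduce the boundary matrix over GF(2) to pair births with deaths, yielding
   a barcode of half-open persistence intervals [b, d) per homology
   dimension.

Only dimensions 0 (connected components) and 1 (independent cycles) are
computed, so simplices up to dimension 2 (triangles) suffice.  The persistent
Betti number β_k^{i,j} counts dimension-k classes born by index i and still
alive after index j; β_1^{1,1} — the number of independent cycles of length
4 or more — is the network complexity score used throughout the package
("nominal Betti").  Classes unpaired within the truncated filtration are
reported with infinite death (right-censored at t_max).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterator

import networkx as nx

from .network import PPINetwork

__all__ = [
    "Simplex",
    "FilteredComplex",
    "Barcode",
    "shortest_path_metric",
    "build_rips",
    "persistent_homology",
    "persistent_betti",
    "nominal_betti",
    "write_barcode_tsv",
    "plot_barcode",
]

DEFAULT_T_MAX = 3
DEFAULT_MAX_DIM = 2


@dataclass(frozen=True, order=True)
class Simplex:
    """A simplex with its filtration birth index.

    Ordering is (birth, dimension, vertices), which is a valid filtration
    order: every face has smaller birth or, at equal birth, smaller
    dimension, hence precedes its cofaces.
    """

    birth: int
    dim: int
    vertices: tuple[str, ...]

    @staticmethod
    def make(vertices: tuple[str, ...], birth: int) -> "Simplex":
        vs = tuple(sorted(set(vertices)))
        if len(vs) != len(vertices):
            raise ValueError(f"simplex vertices must be distinct: {vertices}")
        return Simplex(birth=birth, dim=len(vs) - 1, vertices=vs)

    def faces(self) -> Iterator[tuple[str, ...]]:
        if self.dim == 0:
            return iter(())
        return combinations(self.vertices, self.dim)


@dataclass(frozen=True)
class FilteredComplex:
    """A filtration-ordered, face-closed sequence of simplices."""

    simplices: tuple[Simplex, ...]
    t_max: int
    max_dim: int

    def validate(self) -> None:
        """Raise if the simplex sequence is unordered or not face-closed."""
        index = {}
        for pos, s in enumerate(self.simplices):
            if pos and self.simplices[pos - 1] > s:
                raise ValueError(
                    f"simplices not in filtration order at position {pos}"
                )
            for f in s.faces():
                fi = index.get(f)
                if fi is None:
                    raise ValueError(
                        f"complex not face-closed: face {f} of {s.vertices} missing"
                    )
                if self.simplices[fi].birth > s.birth:
                    raise ValueError(
                        f"face {f} born after coface {s.vertices}"
                    )
            index[s.vertices] = pos


def shortest_path_metric(net: PPINetwork) -> dict[str, dict[str, int]]:
    """All-pairs hop distances d(u, v) with unit edge lengths.

    Returns a nested mapping containing only the finite entries; pairs in
    different components are absent (distance infinite).
    """
    return {u: dict(d) for u, d in nx.all_pairs_shortest_path_length(net)}


def build_rips(
    net: PPINetwork,
    t_max: int = DEFAULT_T_MAX,
    max_dim: int = DEFAULT_MAX_DIM,
) -> FilteredComplex:
    """Build the Rips (flag) filtration of the hop metric up to ``t_max``.

    Vertices are born at 0; an edge {v, w} at d(v, w); a triangle at the
    maximum of its three pairwise distances (the flag rule).  Simplices
    whose birth would exceed ``t_max`` are omitted.  Infinite distances
    (disconnected pairs) generate no simplex.
    """
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    if max_dim not in (1, 2):
        raise ValueError("max_dim must be 1 or 2 (only H0 and H1 are computed)")
    dist = shortest_path_metric(net)
    simplices: list[Simplex] = [Simplex.make((v,), 0) for v in net.nodes()]
    for u, v in combinations(sorted(net.nodes()), 2):
        d = dist[u].get(v)
        if d is not None and d <= t_max:
            simplices.append(Simplex.make((u, v), d))
    if max_dim >= 2:
        for u, v, w in combinations(sorted(net.nodes()), 3):
            duv = dist[u].get(v)
            duw = dist[u].get(w)
            dvw = dist[v].get(w)
            if duv is None or duw is None or dvw is None:
                continue
            birth = max(duv, duw, dvw)
            if birth <= t_max:
                simplices.append(Simplex.make((u, v, w), birth))
    simplices.sort()
    return FilteredComplex(
        simplices=tuple(simplices), t_max=t_max, max_dim=max_dim
    )


@dataclass(frozen=True)
class Barcode:
    """Persistence intervals (dim, birth, death); death is ``math.inf`` for
    classes still alive at the end of the truncated filtration."""

    intervals: tuple[tuple[int, int, float], ...]
    t_max: int

    def in_dimension(self, k: int) -> list[tuple[int, float]]:
        """The (birth, death) pairs of dimension-k intervals."""
        return [(b, d) for dim, b, d in self.intervals if dim == k]

    def betti(self, k: int, i: int, j: int | None = None) -> int:
        """Persistent Betti number β_k^{i,j}; ``j`` defaults to ``i``."""
        return persistent_betti(self, k, i, i if j is None else j)


def persistent_homology(complex: FilteredComplex) -> Barcode:
    """Pair births and deaths by boundary-matrix reduction over GF(2).

    Columns are processed in filtration order; each column is XOR-reduced
    against earlier columns sharing its pivot (lowest remaining face, i.e.
    highest set bit).  A column reducing to zero creates a homology class; a
    surviving pivot kills the class created by that pivot simplex.  Classes
    of zero persistence (birth == death) are discarded.  Intervals are
    reported for dimensions below ``complex.max_dim``, the range on which a
    complex with simplices up to that dimension is conclusive.
    """
    complex.validate()
    simplices = complex.simplices
    index = {s.vertices: i for i, s in enumerate(simplices)}

    # column i encoded as an int bitmask over face row-indices
    pivot_owner: dict[int, int] = {}
    reduced: dict[int, int] = {}
    killed: set[int] = set()
    intervals: list[tuple[int, int, float]] = []

    for j, s in enumerate(simplices):
        col = 0
        for f in s.faces():
            col |= 1 << index[f]
        while col:
            low = col.bit_length() - 1
            owner = pivot_owner.get(low)
            if owner is None:
                break
            col ^= reduced[owner]
        if col:
            low = col.bit_length() - 1
            pivot_owner[low] = j
            reduced[j] = col
            killed.add(low)
            birth_s, death_s = simplices[low], s
            if death_s.birth > birth_s.birth and birth_s.dim < complex.max_dim:
                intervals.append((birth_s.dim, birth_s.birth, death_s.birth))

    for j, s in enumerate(simplices):
        if j not in reduced and j not in killed and s.dim < complex.max_dim:
            intervals.append((s.dim, s.birth, math.inf))

    intervals.sort(key=lambda t: (t[0], t[1], t[2]))
    return Barcode(intervals=tuple(intervals), t_max=complex.t_max)


def persistent_betti(barcode: Barcode, k: int, i: int, j: int) -> int:
    """β_k^{i,j}: dimension-k classes with birth <= i and death > j.

    Infinite deaths count; the half-open interval convention [b, d) makes
    β_0^{0,j} the number of connected components for every j >= 1.
    """
    if i < 0 or i > j:
        raise ValueError(f"need 0 <= i <= j, got i={i}, j={j}")
    return sum(
        1 for dim, b, d in barcode.intervals if dim == k and b <= i and d > j
    )


def nominal_betti(
    net: PPINetwork,
    t_max: int = DEFAULT_T_MAX,
) -> int:
    """The network complexity score β_1^{1,1}: independent cycles of length
    four or more.

    Computed as the persistent Betti number of dimension 1 from filtration
    index 1 to 1 of the Rips filtration (triangles included, so 3-cycles
    bound immediately and are not counted).  Equivalently, the GF(2) rank of
    the cycle space of the graph modulo its triangle boundaries.
    """
    barcode = persistent_homology(build_rips(net, t_max=t_max, max_dim=2))
    return persistent_betti(barcode, 1, 1, 1)


def write_barcode_tsv(barcode: Barcode, path) -> None:
    """Write intervals as TSV with columns dim, birth, death ('inf')."""
    with open(path, "w") as fh:
        fh.write("dim\tbirth\tdeath\n")
        for dim, b, d in barcode.intervals:
            death = "inf" if math.isinf(d) else str(int(d))
            fh.write(f"{dim}\t{b}\t{death}\n")


def plot_barcode(barcode: Barcode, path=None):
    """Plot dimension-0 and dimension-1 bars against the filtration index.

    Requires matplotlib; returns the figure.  Infinite bars are drawn to
    ``t_max + 1`` with an open marker.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(6, 4))
    for ax, k in zip(axes, (0, 1)):
        bars = barcode.in_dimension(k)
        for y, (b, d) in enumerate(sorted(bars)):
            right = barcode.t_max + 1 if math.isinf(d) else d
            ax.hlines(y, b, right, lw=2)
            if math.isinf(d):
                ax.plot(right, y, marker=">", ms=4)
        ax.set_ylabel(f"$H_{k}$")
        ax.set_yticks([])
    axes[-1].set_xlabel("filtration index t")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
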