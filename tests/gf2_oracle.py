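"""Independent brute-force oracle for homology of the flag complex at t = 1.

Deliberately avoids all persistence machinery: the index-1 one-dimensional
Betti number is computed from plain GF(2) linear algebra on the graph's
boundary matrices —

    dim Z_1 = |E| - rank(d1)          (edge boundary matrix, vertex rows)
    dim B_1 = rank(d2)                (triangle boundary matrix, edge rows)
    betti   = dim Z_1 - dim B_1

Vectors are encoded as Python ints (bitmasks) and ranked by Gaussian
elimination.
"""

from itertools import combinations


def gf2_rank(vectors):
    """Rank of a list of GF(2) vectors encoded as int bitmasks."""
    pivots = {}
    rank = 0
    for v in vectors:
        while v:
            high = v.bit_length() - 1
            if high not in pivots:
                pivots[high] = v
                rank += 1
                break
            v ^= pivots[high]
    return rank


def oracle_betti11(graph):
    """dim Z1 - dim B1 of the flag complex at filtration index 1."""
    nodes = sorted(graph.nodes())
    vidx = {v: i for i, v in enumerate(nodes)}
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    eidx = {e: i for i, e in enumerate(edges)}

    d1 = [(1 << vidx[u]) | (1 << vidx[v]) for u, v in edges]
    z1 = len(edges) - gf2_rank(d1)

    d2 = []
    for u, v, w in combinations(nodes, 3):
        tri = [(u, v), (u, w), (v, w)]
        if all(graph.has_edge(*e) for e in tri):
            col = 0
            for e in tri:
                col |= 1 << eidx[tuple(sorted(e))]
            d2.append(col)
    return z1 - gf2_rank(d2)


def oracle_betti2_at_t1(graph):
    """dim H2 of the 2-skeleton flag complex at t=1 (no 3-simplices, so
    H2 = ker d2); used only for Euler-characteristic cross-checks."""
    nodes = sorted(graph.nodes())
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    eidx = {e: i for i, e in enumerate(edges)}
    d2 = []
    n_tri = 0
    for u, v, w in combinations(nodes, 3):
        tri = [(u, v), (u, w), (v, w)]
        if all(graph.has_edge(*e) for e in tri):
            n_tri += 1
            col = 0
            for e in tri:
                col |= 1 << eidx[tuple(sorted(e))]
            d2.append(col)
    return n_tri - gf2_rank(d2)
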