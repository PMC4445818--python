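# Methods

## Model and assumptions

`ppitopo` treats a PPI network as an undirected simple graph with opaque
string node identifiers. All structure beyond connectivity — edge direction,
interaction type, expression levels, mutation status — is deliberately
ignored: the method scores the *topology* of the curated network, nothing
else. Inputs are symmetrised, duplicate edges merged, and self-loops dropped
(they contribute nothing to the hop metric or the cycle space; curated
pathway exports occasionally contain them, so they are a warning, not an
error).

### The filtration

The graph's hop metric (unit edge lengths) induces a Vietoris–Rips flag
filtration: `K^t` holds every vertex, each edge `{u, v}` at birth index
`d(u, v)`, and each triangle at the maximum of its three pairwise distances.
Disconnected pairs have infinite distance and generate no simplex, so every
quantity is well defined on disconnected inputs.

Two truncations are fixed by design:

- **`max_dim = 2`.** Only `H_0` and `H_1` are of interest; computing `H_k`
  correctly needs simplices up to dimension `k + 1`, so triangles suffice.
  Higher-dimensional holes (the octahedron phenomenon) are out of scope.
- **`t_max = 3` (default).** Hole classes of cycles of length `3t` or less
  die by index `t + 1`; at unit hop distances, index 3 already kills every
  cycle of length ≤ 9 and the score `β_1^{1,1}` depends only on `K^1`
  anyway (a property asserted in the tests:
  `nominal_betti(net, t_max=1) == nominal_betti(net, t_max=3)`). Classes
  unpaired at `t_max` are reported with infinite death — right-censored
  within the truncated filtration, not claimed immortal.

### The reduction

Persistence is computed by standard boundary-matrix column reduction over
GF(2). Columns are processed in the filtration order (birth, dimension,
lexicographic vertex tuple) — any valid order gives identical Betti
numbers; the tie-break is fixed only so that pairings are reproducible.
Columns are Python ints used as bitmasks; reduction XORs a column against
the owner of its current pivot (highest set bit) until the pivot is free or
the column vanishes. Zero-persistence pairs (birth = death) are discarded;
intervals are half-open `[b, d)`, so `β_k^{i,j}` counts intervals with
`birth ≤ i < j < death` and `β_0^{0,j}` equals the number of connected
components for every `j ≥ 1`.

The worked 9-node example (two squares joined by a triangle) pins down every
convention: nine dimension-0 bars born at 0, eight dying at 1; two
dimension-1 bars `[1, 2)`; the triangle's cycle killed instantly by the
2-simplex on its own vertices; and a lone 7-cycle yielding one bar `[1, 3)`.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `t_max` | 3 | filtration truncation index (integer hops) |
| `max_dim` | 2 | largest simplex dimension (triangles) |
| `candidate_limit` | off | restrict the pair scan to the top-N single targets |

Degree-entropy uses the natural logarithm (nats); base 2 would rescale every
reported value. Betweenness is unnormalised and counts unordered pairs once,
with fractional credit when shortest paths are tied; it is used only to rank
knockout targets of equal effect, for which any fixed normalisation is
equivalent — the convention is therefore documented rather than load-bearing.
The cycle basis comes from spanning-tree fundamental cycles (Paton's
method via networkx); only its dimension `|E| − |V| + #components` is
reported, and any valid basis has it.

## Knockout scans

A knockout removes the node(s) and all incident edges — the node is dropped,
not isolated, which is what makes component counts meaningful (a hub
bridging two sub-networks splits the graph when removed). The single scan is
O(n) persistence runs and the default double scan O(n²); at the desk scale
of curated pathway networks (≲ 100 nodes) this is thousands of runs on
small complexes and completes in minutes; `candidate_limit` exists as an
optimisation, off by default. Equivalence of targets is exact integer
equality of the post-knockout score. Ranking is by (score ascending,
betweenness of the removed node descending, label), betweenness being the
maximum over the pair for doubles — a documented heuristic, not part of the
homology.

Two structural facts are asserted as tests rather than assumed: removing a
degree-1 node never changes `β_1^{1,1}` (a leaf lies on no cycle), and
`best(double) ≤ best(single) ≤ nominal` on every network.

## Survival map

The survival model is a deliberately plain OLS line
`survival = slope · betti + intercept` with the Pearson correlation and its
two-sided t-test p-value (n − 2 degrees of freedom) — with a panel of 11
cancers, anything richer (a parabola, regularisation) would overfit, and the
t-based p-value is the conventional estimator at this n. The packaged
reference panel gives `r = −0.551`, `p = 0.0789`, slope `−0.382` percent
survival per unit of Betti. A knockout's predicted survival gain is
`slope · (betti_after − betti_before)`, and the returned object carries an
explicit caveat: the fit is population-level across cancer types; the
number is a screening heuristic. Note one internal tension in the reference
panel: the correlation between the nominal Betti and cycle-basis columns
evaluates to 0.965 from the packaged values, while 0.93 has also been
reported for this panel; the package asserts only what its own data
computes.

## Synthetic networks

`generate_synthetic` plants vertex-disjoint cycles of requested lengths and
joins all pieces (cycles plus optional bridge nodes) into one connected
component by a random tree of inter-component edges, so no unplanned cycle
can arise. The analytic score is therefore exact: `β_1^{1,1}` equals the
number of planted cycles of length ≥ 4, recorded in the graph metadata,
and `|E| − |V| + 1` equals the total number of planted cycles. Generation is
deterministic per seed.

What the generator emulates is cycle structure and peripheral (leaf/bridge)
nodes; what it does **not** emulate is the degree heterogeneity, hub
redundancy and dense overlap of real pathway networks, where cycles share
nodes and a single hub removal can destroy many classes at once. Passing the
parameter-recovery tests therefore certifies the engine's arithmetic on
known topology, not biological fidelity of target rankings on real networks.

## Numerical and degenerate-input choices

- All homology is exact integer/GF(2) arithmetic — no floating-point
  tolerances anywhere in the engine.
- Empty networks: degree-entropy and scans refuse (undefined / nothing to
  scan); a network with nodes but no edges is fine everywhere.
- Constant input to the Pearson correlation is an error (undefined), as is
  a panel of fewer than 3 records.
- Component counting after a knockout is computed twice — as `β_0^{0,1}` of
  the residual filtration and by graph traversal — and the two must agree.

## Verification strategy

The engine is continuously checked against an independent oracle that uses
no persistence machinery: `dim Z_1 − dim B_1` of `K^1` from brute-force
GF(2) Gaussian elimination on the edge-boundary and triangle-boundary
matrices. Equivalence is asserted on 500 random graphs of up to 12 nodes,
before and after every single-node knockout, alongside level-wise checks
that `β_k^{t,t}` matches plain homology of the distance-`t` thresholded
graph and that the Euler characteristic balances at every level. Problem
sizes (≤ 12-node random graphs, ≤ ~30-node synthetics) keep the whole suite
in the seconds range while exercising every code path; the engine itself has
no size limit beyond memory.

## Known limitations

- Homology of dimension ≥ 2, weighted-edge filtrations and witness/lazy
  complexes are not implemented.
- Pathway-database conversion (KGML parsing, identifier mapping) is out of
  scope; networks are consumed as prepared edge or adjacency lists.
- The triangle enumeration is O(n³) at dense scales `t ≥ 2`; for networks
  far beyond pathway size a sparse neighbour-intersection enumeration would
  be needed.
- The survival interpolation inherits every caveat of an 11-point
  population-level fit; it must not be read as a patient-level effect size.
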