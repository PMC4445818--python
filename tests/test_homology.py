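import math

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_graph, thresholded_graph
from gf2_oracle import oracle_betti11, oracle_betti2_at_t1

from ppitopo import (
    build_rips,
    nominal_betti,
    persistent_betti,
    persistent_homology,
    shortest_path_metric,
)
from ppitopo.homology import FilteredComplex, Simplex


def cycle(n):
    return nx.relabel_nodes(nx.cycle_graph(n), str)


class TestShortestPathMetric:
    def test_self_distance_zero(self, fig1):
        d = shortest_path_metric(fig1)
        assert all(d[v][v] == 0 for v in fig1)

    def test_fig1_cross_cycle_distance(self, fig1):
        d = shortest_path_metric(fig1)
        assert d["2"]["5"] == 2  # via hub 1
        assert d["3"]["7"] == 5  # 3-2-1-5-6-7 (or the symmetric routes)

    def test_symmetry(self, fig1):
        d = shortest_path_metric(fig1)
        for u in fig1:
            for v in fig1:
                assert d[u].get(v) == d[v].get(u)

    def test_disconnected_pairs_absent(self):
        net = nx.Graph([("A", "B"), ("C", "D")])
        d = shortest_path_metric(net)
        assert "C" not in d["A"]


class TestBuildRips:
    def test_t0_is_vertices_only(self, fig1):
        fc = build_rips(fig1, t_max=0)
        assert len(fc.simplices) == 9
        assert all(s.dim == 0 and s.birth == 0 for s in fc.simplices)

    def test_t1_has_graph_edges_and_the_one_triangle(self, fig1):
        fc = build_rips(fig1, t_max=1)
        edges = [s for s in fc.simplices if s.dim == 1]
        tris = [s for s in fc.simplices if s.dim == 2]
        assert len(edges) == 11 and all(s.birth == 1 for s in edges)
        assert [t.vertices for t in tris] == [("1", "5", "9")]

    def test_t2_adds_distance_two_chords(self, fig1):
        fc = build_rips(fig1, t_max=2)
        born2 = {s.vertices for s in fc.simplices if s.dim == 1 and s.birth == 2}
        assert {("1", "3"), ("2", "4"), ("5", "7"), ("6", "8")} <= born2

    def test_flag_rule_triangle_birth_is_max_pairwise_distance(self, fig1):
        fc = build_rips(fig1, t_max=3)
        births = {s.vertices: s.birth for s in fc.simplices}
        assert births[("1", "2", "3")] == 2  # chord {1,3} arrives at 2

    def test_no_cross_component_simplices(self):
        net = nx.Graph([("A", "B"), ("C", "D")])
        fc = build_rips(net, t_max=3)
        for s in fc.simplices:
            comp = {"A", "B"} if s.vertices[0] in "AB" else {"C", "D"}
            assert set(s.vertices) <= comp

    def test_validate_accepts_own_output(self, fig1):
        build_rips(fig1).validate()

    def test_bad_parameters(self, fig1):
        with pytest.raises(ValueError):
            build_rips(fig1, t_max=-1)
        with pytest.raises(ValueError):
            build_rips(fig1, max_dim=3)


class TestPersistentHomology:
    def test_fig1_dimension0_barcode(self, fig1):
        bc = persistent_homology(build_rips(fig1))
        bars = bc.in_dimension(0)
        assert len(bars) == 9
        assert all(b == 0 for b, _ in bars)
        assert sorted(d for _, d in bars) == [1] * 8 + [math.inf]

    def test_fig1_dimension1_barcode(self, fig1):
        bc = persistent_homology(build_rips(fig1))
        assert bc.in_dimension(1) == [(1, 2), (1, 2)]

    def test_seven_cycle_class_lasts_from_1_to_3(self):
        bc = persistent_homology(build_rips(cycle(7)))
        assert bc.in_dimension(1) == [(1, 3)]

    @pytest.mark.parametrize("n,death", [(4, 2), (5, 2), (6, 2)])
    def test_short_cycles_die_at_two(self, n, death):
        bc = persistent_homology(build_rips(cycle(n)))
        assert bc.in_dimension(1) == [(1, death)]

    def test_triangle_has_no_dimension1_class(self):
        bc = persistent_homology(build_rips(cycle(3)))
        assert bc.in_dimension(1) == []

    def test_unordered_complex_rejected(self, fig1):
        fc = build_rips(fig1)
        shuffled = FilteredComplex(
            simplices=tuple(reversed(fc.simplices)),
            t_max=fc.t_max,
            max_dim=fc.max_dim,
        )
        with pytest.raises(ValueError):
            persistent_homology(shuffled)

    def test_non_face_closed_complex_rejected(self):
        fc = FilteredComplex(
            simplices=(Simplex.make(("a",), 0), Simplex.make(("a", "b"), 1)),
            t_max=1,
            max_dim=1,
        )
        with pytest.raises(ValueError):
            persistent_homology(fc)

    def test_infinite_dim0_bars_count_components(self):
        net = nx.Graph([("A", "B"), ("C", "D"), ("E", "F")])
        bc = persistent_homology(build_rips(net))
        infinite = [b for b, d in bc.in_dimension(0) if math.isinf(d)]
        assert len(infinite) == 3


class TestPersistentBetti:
    def test_fig1_printed_values(self, fig1):
        bc = persistent_homology(build_rips(fig1))
        assert persistent_betti(bc, 0, 0, 0) == 9
        assert persistent_betti(bc, 0, 0, 1) == 1
        assert persistent_betti(bc, 1, 1, 1) == 2
        assert persistent_betti(bc, 1, 1, 2) == 0

    def test_component_count_for_all_j(self, fig1):
        bc = persistent_homology(build_rips(fig1))
        for j in (1, 2, 3):
            assert persistent_betti(bc, 0, 0, j) == 1

    def test_invalid_index_order(self, fig1):
        bc = persistent_homology(build_rips(fig1))
        with pytest.raises(ValueError):
            persistent_betti(bc, 1, 2, 1)

    @pytest.mark.parametrize("seed", range(25))
    def test_betti_at_each_level_matches_thresholded_graph_oracle(self, seed):
        """beta_k^{t,t} equals plain homology of the flag complex of the
        distance-t thresholded graph, and Euler characteristic balances."""
        net = random_graph(seed)
        bc = persistent_homology(build_rips(net, t_max=3))
        for t in range(4):
            gt = thresholded_graph(net, t)
            assert persistent_betti(bc, 0, t, t) == nx.number_connected_components(gt)
            assert persistent_betti(bc, 1, t, t) == oracle_betti11(gt)
            # Euler: V - E + T = b0 - b1 + b2 for the 2-skeleton at level t
            n_tri = sum(
                1
                for s in build_rips(net, t_max=3).simplices
                if s.dim == 2 and s.birth <= t
            )
            chi = gt.number_of_nodes() - gt.number_of_edges() + n_tri
            b2 = oracle_betti2_at_t1(gt)
            assert chi == (
                persistent_betti(bc, 0, t, t) - persistent_betti(bc, 1, t, t) + b2
            )


class TestNominalBetti:
    def test_single_square(self):
        assert nominal_betti(cycle(4)) == 1

    def test_fig1(self, fig1):
        assert nominal_betti(fig1) == 2

    def test_triangle_chain_scores_zero(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d"), ("d", "e"), ("e", "c")])
        assert nominal_betti(net) == 0

    def test_insensitive_to_truncation_index(self, fig1):
        assert nominal_betti(fig1, t_max=1) == nominal_betti(fig1, t_max=3) == 2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_relabeling_invariance(self, seed):
        net = random_graph(seed)
        perm = {v: f"z{hash((seed, v)) % 10**6}_{v}" for v in net}
        assert nominal_betti(net) == nominal_betti(nx.relabel_nodes(net, perm))

    def test_bounded_by_cycle_space_dimension(self, fig1):
        from ppitopo import cycle_basis

        assert nominal_betti(fig1) <= cycle_basis(fig1).dimension
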