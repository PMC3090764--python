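"""Transformation chain and iterative-compression bipartization."""

import numpy as np
import pytest

from pedphase2 import (NEG, POS, BipartizationInstance, Color, SignedGraph,
                       bipartization_bruteforce, compress, edge_bipartization,
                       line_index_bruteforce, merge_and_guard, min_edge_cut,
                       negate_weights, random_multigraph, random_signed_graph,
                       solve_line_index, to_all_negative,
                       two_coloring_from_removal)


def cycle(n, sign=POS, color=Color.GREY):
    g = SignedGraph()
    for i in range(n):
        g.add_vertex(i, color)
    for i in range(n):
        g.add_edge(i, (i + 1) % n, sign)
    return g


class TestToAllNegative:
    def test_all_negative_input_unchanged(self):
        g = cycle(4, NEG)
        out = to_all_negative(g)
        assert out.num_edges == 4 and out.num_vertices == 4

    def test_single_positive_edge_becomes_path(self):
        g = SignedGraph()
        g.add_vertex("a", Color.GREY)
        g.add_vertex("b", Color.GREY)
        g.add_edge("a", "b", POS)
        out = to_all_negative(g)
        assert out.num_vertices == 3 and out.num_edges == 2
        assert all(e.sign == NEG for e in out.edges())
        assert line_index_bruteforce(out)[0] == 0

    def test_line_index_invariant(self, rng):
        for _ in range(100):
            g = random_signed_graph(rng)
            assert line_index_bruteforce(g)[0] == \
                line_index_bruteforce(to_all_negative(g))[0]


class TestMergeAndGuard:
    def test_guard_count(self):
        g = SignedGraph()
        for v, c in [("r1", Color.RED), ("r2", Color.RED),
                     ("g1", Color.GREEN)]:
            g.add_vertex(v, c)
        g.add_edge("r1", "g1", NEG)
        merged, info = merge_and_guard(g, k=2)
        assert merged.num_vertices == 2
        assert len(info.guard_eids) == 3  # k + 1
        assert info.merged[info.red_node] == ["r1", "r2"]

    def test_all_grey_untouched(self):
        g = cycle(5, NEG)
        merged, info = merge_and_guard(g, k=1)
        assert merged.num_vertices == 5 and info.red_node is None

    def test_solution_separates_supernodes(self, rng):
        """Any within-budget solution puts the supernodes on opposite
        sides (pigeonhole over the k+1 parallel guards)."""
        for _ in range(30):
            g = random_signed_graph(rng, max_vertices=7, max_edges=9,
                                    grey_fraction=0.4)
            l = line_index_bruteforce(g)[0]
            sol = solve_line_index(g, k=l)
            assert sol is not None and sol[0] == l


class TestNegateWeights:
    def test_triangle_needs_one_deletion(self):
        inst = negate_weights(cycle(3, NEG))
        assert len(edge_bipartization(inst)) == 1

    def test_even_cycle_needs_none(self):
        inst = negate_weights(cycle(6, NEG))
        assert edge_bipartization(inst) == set()

    def test_empty_graph(self):
        assert edge_bipartization(negate_weights(SignedGraph())) == set()

    def test_rejects_positive_edges(self):
        with pytest.raises(ValueError):
            negate_weights(cycle(3, POS))


class TestMinEdgeCut:
    def test_three_parallel_edges(self):
        edges = [("a", "b")] * 3
        cut = min_edge_cut(edges, {"a"}, {"b"}, limit=3)
        assert sorted(cut) == [0, 1, 2]

    def test_overflow(self):
        edges = [("a", "b")] * 3
        assert min_edge_cut(edges, {"a"}, {"b"}, limit=2) is None

    def test_disconnected_terminals(self):
        edges = [("a", "b"), ("c", "d")]
        assert min_edge_cut(edges, {"a", "b"}, {"c"}, limit=5) == []

    def test_matches_bruteforce(self, rng):
        from itertools import combinations

        def reachable(edges, skip, frm):
            seen = set(frm)
            changed = True
            while changed:
                changed = False
                for i, (u, v) in enumerate(edges):
                    if i in skip:
                        continue
                    if u in seen and v not in seen:
                        seen.add(v); changed = True
                    if v in seen and u not in seen:
                        seen.add(u); changed = True
            return seen

        for _ in range(40):
            n = int(rng.integers(3, 7))
            m = int(rng.integers(1, 9))
            edges = [tuple(map(int, rng.choice(n, 2, replace=False)))
                     for _ in range(m)]
            cut = min_edge_cut(edges, {0}, {n - 1}, limit=m)
            best = None
            for size in range(m + 1):
                for combo in combinations(range(m), size):
                    if n - 1 not in reachable(edges, set(combo), {0}):
                        best = size
                        break
                if best is not None:
                    break
            assert len(cut) == best


class TestEdgeBipartization:
    def test_odd_cycle(self):
        assert len(edge_bipartization(cycle(5))) == 1

    def test_two_disjoint_triangles(self):
        g = SignedGraph()
        for i in range(6):
            g.add_vertex(i, Color.GREY)
        for a, b in [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)]:
            g.add_edge(a, b, POS)
        assert len(edge_bipartization(g)) == 2

    def test_k4(self):
        g = SignedGraph()
        for i in range(4):
            g.add_vertex(i, Color.GREY)
        for a in range(4):
            for b in range(a + 1, 4):
                g.add_edge(a, b, POS)
        assert len(edge_bipartization(g)) == len(bipartization_bruteforce(g))

    def test_budget_aborts(self):
        g = cycle(3)
        assert edge_bipartization(g, budget=0) is None
        assert len(edge_bipartization(g, budget=1)) == 1

    def test_removal_makes_bipartite(self, rng):
        for _ in range(60):
            g = random_multigraph(rng)
            c = edge_bipartization(g)
            assert len(c) == len(bipartization_bruteforce(g))
            two_coloring_from_removal(g, c)  # raises on odd cycle


class TestCompress:
    def test_even_cycle_compresses_to_empty(self):
        g = cycle(4)
        edges = g.edges()
        assert compress(edges, [edges[0]]) == []

    def test_triangle_cannot_compress(self):
        g = cycle(3)
        edges = g.edges()
        assert compress(edges, [edges[0]]) is None

    def test_succeeds_iff_bruteforce_smaller(self, rng):
        for _ in range(40):
            g = random_multigraph(rng, max_vertices=7, max_edges=10)
            opt = len(bipartization_bruteforce(g))
            full = edge_bipartization(g)
            edges = [e for e in g.edges() if not e.is_loop]
            xprime = [g.edge(eid) for eid in sorted(full) if g.has_edge(eid)
                      and not g.edge(eid).is_loop]
            if not xprime:
                continue
            y = compress(edges, xprime)
            loops = sum(1 for e in g.edges() if e.is_loop)
            assert (y is not None) == (opt - loops <= len(xprime) - 1)


class TestTwoColoring:
    def test_even_cycle_proper(self):
        sides = two_coloring_from_removal(cycle(4), set())
        assert all(sides[i] != sides[(i + 1) % 4] for i in range(4))

    def test_triangle_after_removal(self):
        g = cycle(3)
        eid = g.edges()[0].eid
        sides = two_coloring_from_removal(g, {eid})
        e = g.edge(eid)
        assert sides[e.u] == sides[e.v]  # the removed edge is monochromatic

    def test_odd_cycle_raises(self):
        with pytest.raises(ValueError):
            two_coloring_from_removal(cycle(3), set())


def test_full_chain_recovers_line_index(rng):
    """Line index through negative conversion, supernode merging,
    weight negation, compression and back-mapping equals brute force."""
    for _ in range(80):
        g = random_signed_graph(rng)
        l, _ = line_index_bruteforce(g)
        value, colors = solve_line_index(g)
        assert value == l
        from pedphase2 import line_index_of_labeling
        assert line_index_of_labeling(g, colors).value == l
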