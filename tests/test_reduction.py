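"""Data-reduction rules: per-rule behavior, trace replay, soundness."""

import numpy as np
import pytest

from pedphase2 import (NEG, POS, Color, SignedGraph, check_no_instance,
                       forced_label_rules, line_index_bruteforce,
                       line_index_of_labeling, random_signed_graph,
                       reduce_to_fixpoint, replay_trace)


def graph(colors, edges):
    g = SignedGraph()
    for v, c in colors.items():
        g.add_vertex(v, c)
    for u, v, s in edges:
        g.add_edge(u, v, s)
    return g


class TestNoInstanceCheck:
    def test_forced_positive_conflict(self):
        g = graph({"a": Color.RED, "b": Color.GREEN}, [("a", "b", POS)])
        assert check_no_instance(g, 0)
        assert not check_no_instance(g, 1)

    def test_negative_same_color_boundary(self):
        g = graph({"a": Color.GREEN, "b": Color.GREEN}, [("a", "b", NEG)])
        assert not check_no_instance(g, 1)  # exactly 1 <= k

    def test_all_grey_never_no_instance(self):
        g = graph({i: Color.GREY for i in range(4)},
                  [(0, 1, NEG), (1, 2, NEG), (2, 0, NEG)])
        assert not check_no_instance(g, 0)


class TestForcedLabels:
    def test_majority_rule(self):
        colors = {"x": Color.GREY, "g1": Color.GREEN, "g2": Color.GREEN,
                  "y": Color.GREY}
        g = graph(colors, [("x", "g1", POS), ("x", "g2", POS),
                           ("x", "y", NEG)])
        out, no = forced_label_rules(g)
        assert out == {"x": Color.GREEN} and not no

    def test_no_majority_no_forcing(self):
        colors = {"x": Color.GREY, "g1": Color.GREEN,
                  "a": Color.GREY, "b": Color.GREY, "c": Color.GREY}
        g = graph(colors, [("x", "g1", POS), ("x", "a", NEG),
                           ("x", "b", NEG), ("x", "c", NEG)])
        out, _ = forced_label_rules(g)
        assert "x" not in out

    def test_budget_forcing_in_decision_mode(self):
        # one resolved conflict-if-red out of degree two: no majority,
        # but with k=0 the red option is already over budget
        g = graph({"x": Color.GREY, "g1": Color.GREEN, "y": Color.GREY},
                  [("x", "g1", POS), ("x", "y", NEG)])
        out, _ = forced_label_rules(g, k=0)
        assert out.get("x") is Color.GREEN
        out, _ = forced_label_rules(g)
        assert out == {}


class TestIndividualRules:
    def test_isolated_grey_deleted_k_unchanged(self):
        g = graph({"x": Color.GREY}, [])
        res = reduce_to_fixpoint(g, k=3)
        assert res.graph.num_vertices == 0 and res.k == 3
        assert replay_trace(res.trace, {})["x"] is Color.GREEN

    def test_degree_one_grey_follows_neighbor(self):
        g = graph({"u": Color.GREY, "v": Color.GREY, "w": Color.GREY},
                  [("u", "v", NEG), ("v", "w", NEG), ("w", "u", NEG)])
        # triangle of greys: nothing below degree 2... make a pendant
        g.add_vertex("p", Color.GREY)
        g.add_edge("p", "u", NEG)
        res = reduce_to_fixpoint(g)
        colors = replay_trace(res.trace,
                              {v: Color.RED for v in res.graph.vertices()})
        assert colors["p"] is not colors["u"]  # negative edge: opposite

    @pytest.mark.parametrize("sign,same,delta", [
        (NEG, True, 1), (POS, True, 0), (POS, False, 1), (NEG, False, 0)])
    def test_resolved_resolved_edges(self, sign, same, delta):
        cb = Color.RED if same else Color.GREEN
        g = graph({"a": Color.RED, "b": cb}, [("a", "b", sign)])
        res = reduce_to_fixpoint(g, k=5)
        assert res.graph.num_edges == 0
        assert res.cost == delta and res.k == 5 - delta

    def test_rule7_pos_pos_opposite_costs_one(self):
        g = graph({"x": Color.GREY, "u": Color.RED, "v": Color.GREEN},
                  [("u", "x", POS), ("x", "v", POS)])
        res = reduce_to_fixpoint(g, k=2)
        assert res.cost == 1 and "x" not in res.graph

    def test_rule7_neg_neg_grey_becomes_positive_edge(self):
        g = graph({"x": Color.GREY, "u": Color.GREY, "v": Color.GREY,
                   "a": Color.GREY, "b": Color.GREY},
                  [("u", "x", NEG), ("x", "v", NEG),
                   ("u", "a", POS), ("a", "v", POS),
                   ("u", "b", NEG), ("b", "v", NEG)])
        res = reduce_to_fixpoint(g)
        assert res.cost == 0
        # x and b both collapse; replay must reproduce the optimum
        l, colors = line_index_bruteforce(res.graph)
        full = replay_trace(res.trace, colors)
        assert line_index_of_labeling(g, full).value == \
            line_index_bruteforce(g)[0]

    def test_rule7_merge_keeps_answer(self):
        # grey x between grey u (positive) and grey v (positive): merge
        g = graph({"x": Color.GREY, "u": Color.GREY, "v": Color.GREY,
                   "r": Color.RED},
                  [("u", "x", POS), ("x", "v", POS), ("u", "r", NEG),
                   ("v", "r", NEG), ("u", "v", NEG)])
        l0 = line_index_bruteforce(g)[0]
        res = reduce_to_fixpoint(g)
        assert res.cost + line_index_bruteforce(res.graph)[0] == l0

    def test_parallel_edges_to_one_neighbor(self):
        # mixed-sign parallel pair always costs exactly one
        g = graph({"x": Color.GREY, "u": Color.GREY, "r": Color.RED,
                   "s": Color.RED},
                  [("x", "u", POS), ("x", "u", NEG),
                   ("u", "r", NEG), ("u", "s", NEG)])
        l0 = line_index_bruteforce(g)[0]
        res = reduce_to_fixpoint(g)
        assert all(res.graph.degree(v) >= 3
                   for v in res.graph.grey_vertices())
        assert res.cost + line_index_bruteforce(res.graph)[0] == l0


class TestTraceAccounting:
    def test_k_delta_sums_to_cost(self, rng):
        for _ in range(50):
            g = random_signed_graph(rng)
            res = reduce_to_fixpoint(g)
            assert sum(r.k_delta for r in res.trace) == res.cost

    def test_trace_serializes_to_json(self, rng):
        import json

        from pedphase2.reduction import trace_to_json

        res = reduce_to_fixpoint(random_signed_graph(rng))
        dumped = json.dumps(trace_to_json(res.trace))
        assert json.loads(dumped) == trace_to_json(res.trace)

    def test_replay_reproduces_optimum_exactly(self, rng):
        for _ in range(100):
            g = random_signed_graph(rng)
            res = reduce_to_fixpoint(g)
            l_red, colors_red = line_index_bruteforce(res.graph)
            full = replay_trace(res.trace, colors_red)
            li = line_index_of_labeling(g, full)
            assert li.value == line_index_bruteforce(g)[0]
            assert li.value == res.cost + l_red


def test_decision_answers_preserved(rng):
    """Reduced instance answers (optimum <= k) identically, and leaves
    no grey vertex of degree below three."""
    for _ in range(150):
        g = random_signed_graph(rng)
        l, _ = line_index_bruteforce(g)
        for k in range(4):
            res = reduce_to_fixpoint(g, k=k)
            if res.no_instance:
                assert l > k
            else:
                assert (line_index_bruteforce(res.graph)[0] <= res.k) \
                    == (l <= k)
                assert all(res.graph.degree(v) >= 3
                           for v in res.graph.grey_vertices())
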