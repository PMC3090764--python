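"""Kernelizing data-reduction rules for the signed pedigree graph.

``reduce_to_fixpoint`` shrinks an instance ``(G, k)`` to ``(G', k')``
while preserving the answer exactly: the minimum frustration satisfies
``l(G) = l(G') + (k - k')``, and an optimal labeling of ``G'`` can be
replayed through the recorded trace to an optimal labeling of ``G``.
The rules are

* degree-0 vertices and degree-1 grey vertices are deleted (their color
  can always be chosen for free afterwards);
* an edge between two resolved vertices is deleted, paying one unit of
  budget iff it is frustrated (negative same-label or positive
  opposite-label);
* a grey vertex whose resolved neighbors force one color on a strict
  majority of its incident edges is recolored (safe for minimization by
  a flip argument);
* in decision mode only, a grey vertex whose cheaper color already
  exceeds the remaining budget is forced the other way, or the instance
  is declared a No-instance;
* a grey degree-2 vertex is removed by case analysis on its two edge
  signs and its neighbors' states: deletion (sometimes paying 1),
  merging into a neighbor, or replacement of two negative edges by one
  positive edge.  The paper-style case analysis assumes the two
  neighbors are distinct; the parallel-edge variant (both edges to the
  same neighbor) is handled by the same arguments so that the
  guaranteed postcondition -- no grey vertex of degree less than three
  -- holds unconditionally.

Every deletion/merge appends a :class:`TraceRecord`;
:func:`replay_trace` runs the records backwards to extend a labeling of
the reduced graph to all original vertices.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Any, Hashable, Mapping

from .sgraph import NEG, POS, Color, Edge, SignedGraph, opposite


class TraceMismatchError(RuntimeError):
    """Replay referenced a vertex whose color is unknown."""


@dataclass(frozen=True)
class TraceRecord:
    rule: str
    action: str  # "delete_edge" | "delete_vertex" | "merge" | "recolor"
    vertex: Hashable | None = None
    target: Hashable | None = None   # merge target / reference neighbor
    relation: str | None = None      # "fixed" | "same" | "opposite"
    color: Color | None = None       # for relation == "fixed" and recolors
    edges: tuple[Edge, ...] = ()     # edges removed by this step
    k_delta: int = 0


@dataclass
class ReductionResult:
    graph: SignedGraph
    trace: list[TraceRecord]
    cost: int                 # k - k', the budget consumed by the rules
    k: int | None             # remaining budget (decision mode only)
    no_instance: bool = False


def _frustrated_resolved(edge: Edge, g: SignedGraph) -> bool:
    cu, cv = g.color(edge.u), g.color(edge.v)
    same = cu is cv
    return (edge.sign == NEG and same) or (edge.sign == POS and not same)


def check_no_instance(g: SignedGraph, k: int) -> bool:
    """True iff forced conflicts already exceed the budget.

    Forced conflicts are edges frustrated under *every* completion:
    negative edges between same-labeled resolved vertices, positive
    edges between opposite-labeled resolved vertices, and (degenerate
    input) any negative self-loop.
    """
    forced = 0
    for e in g.edges():
        if e.is_loop:
            forced += e.sign == NEG
        elif g.color(e.u).is_resolved and g.color(e.v).is_resolved:
            forced += _frustrated_resolved(e, g)
    return forced > k


def _conflict_counts(g: SignedGraph, x: Hashable) -> tuple[int, int]:
    """(conflicts if x were red, conflicts if x were green), counting
    multiplicity over resolved neighbors."""
    c_red = c_green = 0
    for e in g.incident(x):
        if e.is_loop:
            continue
        other = g.color(e.other(x))
        if not other.is_resolved:
            continue
        clash_red = (e.sign == POS and other is Color.GREEN) or \
                    (e.sign == NEG and other is Color.RED)
        if clash_red:
            c_red += 1
        else:
            c_green += 1
    return c_red, c_green


def forced_label_rules(g: SignedGraph, k: int | None = None,
                       ) -> tuple[dict[Hashable, Color], bool]:
    """One pass of the forced-labeling observations.

    Always applies the majority rule (a grey vertex is colored so that
    at most half of its incident edges can be frustrated); with a budget
    ``k`` additionally forces colors whose alternative would exceed the
    budget.  Returns ``(assignments, no_instance)``.
    """
    forced_base = 0
    if k is not None:
        for e in g.edges():
            if e.is_loop:
                forced_base += e.sign == NEG
            elif g.color(e.u).is_resolved and g.color(e.v).is_resolved:
                forced_base += _frustrated_resolved(e, g)
    out: dict[Hashable, Color] = {}
    for x in g.grey_vertices():
        c_red, c_green = _conflict_counts(g, x)
        deg = g.degree(x)
        if 2 * c_red > deg:
            out[x] = Color.GREEN
        elif 2 * c_green > deg:
            out[x] = Color.RED
        elif k is not None:
            bad_red = forced_base + c_red > k
            bad_green = forced_base + c_green > k
            if bad_red and bad_green:
                return out, True
            if bad_red:
                out[x] = Color.GREEN
            elif bad_green:
                out[x] = Color.RED
    return out, False


def trace_to_json(trace: list[TraceRecord]) -> list[dict]:
    """JSON-serializable audit log of the rule applications."""
    out = []
    for rec in trace:
        out.append({
            "rule": rec.rule,
            "action": rec.action,
            "vertex": None if rec.vertex is None else str(rec.vertex),
            "target": None if rec.target is None else str(rec.target),
            "relation": rec.relation,
            "color": rec.color.value if rec.color else None,
            "edges": [[str(e.u), str(e.v),
                       "pos" if e.sign == POS else "neg"]
                      for e in rec.edges],
            "k_delta": rec.k_delta,
        })
    return out


class _NoInstance(Exception):
    pass


class _Reducer:
    def __init__(self, g: SignedGraph, k: int | None):
        self.g = g.copy()
        self.k = k
        self.decision = k is not None
        self.cost = 0
        self.trace: list[TraceRecord] = []
        self.queue: deque[Hashable] = deque()
        self.queued: set[Hashable] = set()

    # -- bookkeeping --------------------------------------------------

    def touch(self, *vs: Hashable) -> None:
        for v in vs:
            if v in self.g and v not in self.queued:
                self.queue.append(v)
                self.queued.add(v)

    def pay(self, units: int) -> None:
        self.cost += units
        if self.decision and self.cost > self.k:
            raise _NoInstance

    def record(self, **kw: Any) -> None:
        self.trace.append(TraceRecord(**kw))

    # -- primitive actions --------------------------------------------

    def delete_edge(self, edge: Edge, rule: str, k_delta: int) -> None:
        self.g.remove_edge(edge.eid)
        self.record(rule=rule, action="delete_edge", edges=(edge,),
                    k_delta=k_delta)
        self.pay(k_delta)
        self.touch(edge.u, edge.v)

    def delete_vertex(self, x: Hashable, rule: str, k_delta: int,
                      relation: str, target: Hashable | None = None,
                      color: Color | None = None) -> None:
        neighbors = self.g.neighbors(x)
        removed = tuple(self.g.remove_vertex(x))
        self.record(rule=rule, action="delete_vertex", vertex=x,
                    target=target, relation=relation, color=color,
                    edges=removed, k_delta=k_delta)
        self.pay(k_delta)
        self.touch(*neighbors)

    def merge(self, x: Hashable, into: Hashable, via: Edge, rule: str) -> None:
        """Identify grey ``x`` with its neighbor ``into``: drop the
        connecting edge, rehome the other edge, delete ``x``."""
        self.g.remove_edge(via.eid)
        moved = []
        for e in list(self.g.incident(x)):
            self.g.rehome_edge(e.eid, x, into)
            moved.append(e.other(x))
        self.g.remove_vertex(x)
        self.record(rule=rule, action="merge", vertex=x, target=into,
                    relation="same", edges=(via,), k_delta=0)
        self.touch(into, *moved)

    def recolor(self, x: Hashable, color: Color, rule: str) -> None:
        self.g.set_color(x, color)
        self.record(rule=rule, action="recolor", vertex=x, color=color)
        neighbors = self.g.neighbors(x)
        self.clean_resolved_edges(x)
        self.touch(x, *neighbors)

    def clean_resolved_edges(self, v: Hashable) -> None:
        """Rules 3-6: remove edges joining two resolved vertices."""
        if not self.g.color(v).is_resolved:
            return
        for e in list(self.g.incident(v)):
            u = e.other(v)
            if e.is_loop:
                frustrated = e.sign == NEG
                rule = "R3" if frustrated else "R4"
            elif self.g.color(u).is_resolved:
                frustrated = _frustrated_resolved(e, self.g)
                same = self.g.color(e.u) is self.g.color(e.v)
                rule = {(NEG, True): "R3", (POS, True): "R4",
                        (POS, False): "R5", (NEG, False): "R6"}[(e.sign, same)]
            else:
                continue
            self.delete_edge(e, rule, int(frustrated))

    # -- the worklist -------------------------------------------------

    def run(self) -> None:
        # initial sweep: resolved-resolved edges never survive
        for e in list(self.g.edges()):
            if self.g.has_edge(e.eid) and not e.is_loop and \
                    self.g.color(e.u).is_resolved and self.g.color(e.v).is_resolved:
                same = self.g.color(e.u) is self.g.color(e.v)
                rule = {(NEG, True): "R3", (POS, True): "R4",
                        (POS, False): "R5", (NEG, False): "R6"}[(e.sign, same)]
                self.delete_edge(e, rule, int(_frustrated_resolved(e, self.g)))
        self.touch(*self.g.vertices())
        while self.queue:
            v = self.queue.popleft()
            self.queued.discard(v)
            if v in self.g:
                self.process(v)

    def process(self, v: Hashable) -> None:
        color = self.g.color(v)
        if color.is_resolved:
            self.clean_resolved_edges(v)
            if v in self.g and self.g.degree(v) == 0:
                self.delete_vertex(v, "R1", 0, "fixed", color=color)
            return
        # grey self-loops have a color-independent cost
        for e in list(self.g.incident(v)):
            if e.is_loop:
                self.delete_edge(e, "R3" if e.sign == NEG else "R4",
                                 int(e.sign == NEG))
        deg = self.g.degree(v)
        if deg == 0:
            self.delete_vertex(v, "R1", 0, "fixed", color=Color.GREEN)
            return
        if deg == 1:
            e = self.g.incident(v)[0]
            w = e.other(v)
            self.delete_vertex(v, "R2", 0,
                               "same" if e.sign == POS else "opposite",
                               target=w)
            return
        c_red, c_green = _conflict_counts(self.g, v)
        if 2 * c_red > deg:
            self.recolor(v, Color.GREEN, "Obs3")
            return
        if 2 * c_green > deg:
            self.recolor(v, Color.RED, "Obs3")
            return
        if deg == 2:
            self.rule7(v)
            return
        if self.decision:
            # resolved-resolved edges are cleaned eagerly, so the
            # forced-conflict term is already folded into self.cost
            k_rem = self.k - self.cost
            bad_red = c_red > k_rem
            bad_green = c_green > k_rem
            if bad_red and bad_green:
                raise _NoInstance
            if bad_red:
                self.recolor(v, Color.GREEN, "Obs2")
            elif bad_green:
                self.recolor(v, Color.RED, "Obs2")

    def rule7(self, x: Hashable) -> None:
        e1, e2 = self.g.incident(x)
        u, w = e1.other(x), e2.other(x)
        if u == w:
            # both edges parallel to one neighbor
            signs = {e1.sign, e2.sign}
            if signs == {POS}:
                self.delete_vertex(x, "R7-par", 0, "same", target=u)
            elif signs == {NEG}:
                self.delete_vertex(x, "R7-par", 0, "opposite", target=u)
            else:  # one of the two edges is frustrated whatever x is
                self.delete_vertex(x, "R7-par", 1, "same", target=u)
            return
        if e1.sign == POS and e2.sign == POS:
            self.rule7_pos_pos(x, e1, u, e2, w)
        elif e1.sign == NEG and e2.sign == NEG:
            self.rule7_neg_neg(x, e1, u, e2, w)
        else:
            pe, pu = (e1, u) if e1.sign == POS else (e2, w)
            ne, nw = (e2, w) if e1.sign == POS else (e1, u)
            self.rule7_pos_neg(x, pe, pu, ne, nw)

    def rule7_pos_pos(self, x, e1, u, e2, w) -> None:
        cu, cw = self.g.color(u), self.g.color(w)
        if cu.is_resolved and cw.is_resolved:
            if cu is cw:
                self.delete_vertex(x, "R7-1a", 0, "fixed", color=cu)
            else:
                self.delete_vertex(x, "R7-1b", 1, "fixed", color=cu)
        elif cu.is_resolved:
            self.merge(x, u, e1, "R7-1c")
        elif cw.is_resolved:
            self.merge(x, w, e2, "R7-1c")
        else:
            self.merge(x, u, e1, "R7-1d")

    def rule7_neg_neg(self, x, e1, u, e2, w) -> None:
        cu, cw = self.g.color(u), self.g.color(w)
        if cu.is_resolved and cw.is_resolved:
            if cu is cw:
                self.delete_vertex(x, "R7-2a", 0, "fixed", color=opposite(cu))
            else:
                self.delete_vertex(x, "R7-2b", 1, "fixed", color=opposite(cu))
        elif cu.is_resolved or cw.is_resolved:
            re_, rv = (e1, u) if cu.is_resolved else (e2, w)
            new = opposite(self.g.color(rv))
            self.g.remove_edge(re_.eid)
            self.record(rule="R7-2c", action="delete_edge", edges=(re_,),
                        k_delta=0)
            self.recolor(x, new, "R7-2c")
            self.touch(rv)
        else:
            prov = ("r7-2d", e1.provenance, e2.provenance)
            self.delete_vertex(x, "R7-2d", 0, "opposite", target=u)
            self.g.add_edge(u, w, POS, prov)
            self.touch(u, w)

    def rule7_pos_neg(self, x, pe, pu, ne, nw) -> None:
        cu, cw = self.g.color(pu), self.g.color(nw)
        if cu.is_resolved and cw.is_resolved:
            if cu is cw:
                self.delete_vertex(x, "R7-3a", 1, "fixed", color=cu)
            else:
                self.delete_vertex(x, "R7-3b", 0, "fixed", color=cu)
        elif cu.is_resolved:
            self.merge(x, pu, pe, "R7-3ci")
        elif cw.is_resolved:
            new = opposite(cw)
            self.g.remove_edge(ne.eid)
            self.record(rule="R7-3cii", action="delete_edge", edges=(ne,),
                        k_delta=0)
            self.recolor(x, new, "R7-3cii")
            self.touch(nw)
        else:
            self.merge(x, pu, pe, "R7-3d")


def reduce_to_fixpoint(g: SignedGraph, k: int | None = None) -> ReductionResult:
    """Apply all reduction rules until none fires.

    With ``k`` given (decision mode) the budget-dependent forcing is
    enabled and a ``no_instance`` marker is returned as soon as the
    consumed budget exceeds ``k``.  Without ``k`` (minimization mode)
    only the unconditionally optimum-preserving rules run and ``cost``
    reports the recombinations the rules already committed to.
    The input graph is not modified.
    """
    red = _Reducer(g, k)
    if k is not None and check_no_instance(g, k):
        return ReductionResult(red.g, red.trace, red.cost, None,
                               no_instance=True)
    try:
        red.run()
    except _NoInstance:
        return ReductionResult(red.g, red.trace, red.cost, None,
                               no_instance=True)
    return ReductionResult(red.g, red.trace, red.cost,
                           None if k is None else k - red.cost)


def replay_trace(trace: list[TraceRecord],
                 reduced_colors: Mapping[Hashable, Color],
                 ) -> dict[Hashable, Color]:
    """Extend a labeling of the reduced graph to every original vertex.

    Records are undone in reverse order: merged vertices take their
    alias's color, deleted vertices follow the directive stored when the
    rule fired ("fixed", or same/opposite relative to a reference
    neighbor that is colored by the time the record is replayed).
    """
    colors = dict(reduced_colors)
    for rec in reversed(trace):
        if rec.action == "delete_vertex":
            if rec.relation == "fixed":
                colors[rec.vertex] = rec.color
            else:
                ref = colors.get(rec.target)
                if ref is None:
                    raise TraceMismatchError(
                        f"replay of {rec.rule}: reference vertex "
                        f"{rec.target!r} has no color")
                colors[rec.vertex] = ref if rec.relation == "same" \
                    else opposite(ref)
        elif rec.action == "merge":
            ref = colors.get(rec.target)
            if ref is None:
                raise TraceMismatchError(
                    f"replay of {rec.rule}: merge target {rec.target!r} "
                    "has no color")
            colors[rec.vertex] = ref
    return colors
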