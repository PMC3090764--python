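"""Line index via Bipartization by Edge Removal and iterative compression.

The chain of transformations:

1. ``to_all_negative`` — every positive edge is replaced by two
   consecutive negative edges through a fresh grey vertex; the minimum
   frustration (line index) is unchanged, because the new vertex can
   always be placed on whichever side saves the extra edge.
2. ``merge_and_guard`` — all red vertices are merged into one
   supernode, all green into another, both relabeled grey, and ``k+1``
   parallel negative guard edges are strung between them so that no
   budget-respecting solution may put the two supernodes on one side.
   When no budget is given (pure minimization) ``|E|+1`` guards serve
   the same purpose.
3. ``negate_weights`` — with only negative edges, multiplying every
   weight by -1 turns "frustrated = same side" into "monochromatic
   edge", i.e. the problem of deleting at most ``k`` edges to make the
   graph bipartite.

The bipartization itself is solved by iterative compression: process
edges one at a time, keep an optimal deletion set ``X`` for the current
prefix, and whenever ``X`` stops working compress ``X' = X + {e}`` by
subdividing each ``X'`` edge into three, enumerating the 2^{|X'|-1}
valid two-sidings of the subdivision endpoints and, for each, computing
a unit-capacity minimum edge cut (BFS augmenting paths).  The smallest
cut no larger than ``|X'| - 1`` replaces ``X``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

from .sgraph import NEG, POS, Color, Edge, SignedGraph


@dataclass
class MergeInfo:
    red_node: Hashable | None
    green_node: Hashable | None
    merged: dict[Hashable, list[Hashable]]
    guard_eids: list[int]


@dataclass
class BipartizationInstance:
    """Unsigned multigraph (edge signs ignored) plus deletion budget."""

    graph: SignedGraph
    budget: int | None = None


# ---------------------------------------------------------------------------
# transformations


def to_all_negative(g: SignedGraph) -> SignedGraph:
    """Replace each positive edge by two negative halves through a new
    grey vertex; preserves the line index exactly."""
    out = g.copy()
    for e in g.edges():
        if e.sign != POS:
            continue
        out.remove_edge(e.eid)
        y = ("y", e.eid)
        out.add_vertex(y, Color.GREY)
        out.add_edge(e.u, y, NEG, ("half", e.eid))
        out.add_edge(y, e.v, NEG, ("half", e.eid))
    return out


def merge_and_guard(g: SignedGraph, k: int | None = None,
                    ) -> tuple[SignedGraph, MergeInfo]:
    """Merge color classes into supernodes and add guard edges.

    Expects an all-negative graph.  With both color classes non-empty,
    ``k + 1`` (or ``|E| + 1`` when ``k`` is None) parallel negative
    edges force the supernodes onto opposite sides of any solution
    within budget.  Guard edges are omitted if a class is empty.
    """
    out = g.copy()
    info = MergeInfo(None, None, {}, [])
    for color, node in ((Color.RED, ("super", "red")),
                        (Color.GREEN, ("super", "green"))):
        members = [v for v in out.vertices() if out.color(v) is color]
        if not members:
            continue
        out.add_vertex(node, Color.GREY)
        for v in members:
            for e in list(out.incident(v)):
                out.rehome_edge(e.eid, v, node)
            out.remove_vertex(v)
        info.merged[node] = members
        if color is Color.RED:
            info.red_node = node
        else:
            info.green_node = node
    if info.red_node is not None and info.green_node is not None:
        n_guards = (k + 1) if k is not None else out.num_edges + 1
        for i in range(n_guards):
            eid = out.add_edge(info.red_node, info.green_node, NEG,
                               ("guard", i))
            info.guard_eids.append(eid)
    return out, info


def negate_weights(g: SignedGraph) -> BipartizationInstance:
    """Flip every (negative) weight, yielding the unsigned instance in
    which a labeling's frustrated edges are exactly the monochromatic
    ones."""
    out = SignedGraph()
    for v in g.vertices():
        out.add_vertex(v, g.color(v))
    for e in g.edges():
        if e.sign != NEG:
            raise ValueError("negate_weights expects an all-negative graph")
        out.add_edge(e.u, e.v, POS, e.provenance, eid=e.eid)
    return BipartizationInstance(out)


# ---------------------------------------------------------------------------
# minimum edge cut (unit capacities, BFS augmenting paths)


def min_edge_cut(edges: Sequence[tuple[Hashable, Hashable]],
                 sources: set[Hashable], sinks: set[Hashable],
                 limit: int) -> list[int] | None:
    """Minimum edge cut separating ``sources`` from ``sinks``.

    ``edges`` is a sequence of undirected unit-capacity edges; the
    return value lists the indices of a minimum cut, or ``None``
    (overflow) once more than ``limit`` augmenting paths are needed.
    """
    if sources & sinks:
        raise ValueError("sources and sinks must be disjoint")
    adj: dict[Hashable, list[int]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append(idx)
        adj.setdefault(v, []).append(idx)
    # flow[idx] in {-1, 0, +1}: +1 means one unit from edges[idx][0] to [1]
    flow = [0] * len(edges)

    def residual(idx: int, frm: Hashable) -> int:
        u, v = edges[idx]
        return 1 - flow[idx] if frm == u else 1 + flow[idx]

    def bfs() -> list[tuple[int, Hashable]] | None:
        parent: dict[Hashable, tuple[int, Hashable]] = {}
        q = deque(sorted(sources, key=str))
        seen = set(sources)
        while q:
            x = q.popleft()
            for idx in adj.get(x, ()):
                y = edges[idx][1] if edges[idx][0] == x else edges[idx][0]
                if y in seen or residual(idx, x) <= 0:
                    continue
                parent[y] = (idx, x)
                if y in sinks:
                    path = []
                    while y not in sources:
                        idx2, px = parent[y]
                        path.append((idx2, px))
                        y = px
                    return path
                seen.add(y)
                q.append(y)
        return None

    value = 0
    while True:
        path = bfs()
        if path is None:
            break
        value += 1
        if value > limit:
            return None
        for idx, frm in path:
            flow[idx] += 1 if frm == edges[idx][0] else -1

    # residual reachability gives the cut
    reach = set(sources)
    q = deque(sorted(sources, key=str))
    while q:
        x = q.popleft()
        for idx in adj.get(x, ()):
            y = edges[idx][1] if edges[idx][0] == x else edges[idx][0]
            if y not in reach and residual(idx, x) > 0:
                reach.add(y)
                q.append(y)
    cut = [idx for idx, (u, v) in enumerate(edges)
           if (u in reach) != (v in reach)]
    assert len(cut) == value, "max-flow/min-cut mismatch"
    return cut


# ---------------------------------------------------------------------------
# iterative compression


def _is_bipartite(edge_list: Iterable[Edge], excluded: set[int]) -> bool:
    adj: dict[Hashable, list[Edge]] = {}
    for e in edge_list:
        if e.eid in excluded:
            continue
        if e.is_loop:
            return False
        adj.setdefault(e.u, []).append(e)
        adj.setdefault(e.v, []).append(e)
    side: dict[Hashable, int] = {}
    for start in sorted(adj, key=str):
        if start in side:
            continue
        side[start] = 0
        q = deque([start])
        while q:
            x = q.popleft()
            for e in adj[x]:
                y = e.other(x)
                if y not in side:
                    side[y] = 1 - side[x]
                    q.append(y)
                elif side[y] == side[x]:
                    return False
    return True


def compress(prefix: Sequence[Edge], xprime: Sequence[Edge],
             ) -> list[Edge] | None:
    """Shrink a bipartization set ``xprime`` of the graph spanned by
    ``prefix`` to size ``|xprime| - 1``, or report that none exists.

    Each ``xprime`` edge is subdivided into three consecutive edges (the
    middle one carrying the role of the original, which keeps all cycle
    parities and makes the replacement set disjoint from ``xprime``);
    all valid two-sidings of the subdivision endpoints are enumerated,
    the first edge's orientation being fixed by symmetry, and a minimum
    source/sink edge cut is extracted for each.
    """
    target = len(xprime) - 1
    # the partition-enumeration argument requires a *minimal* set; if a
    # single edge is redundant the remaining set already has target size
    # (supersets of a bipartization set are bipartization sets)
    for e in xprime:
        rest = [d for d in xprime if d.eid != e.eid]
        if _is_bipartite(prefix, {d.eid for d in rest}):
            return rest
    xp_ids = {e.eid for e in xprime}
    flow_edges: list[tuple[Hashable, Hashable]] = []
    backrefs: list[Edge] = []
    middles: list[tuple[Hashable, Hashable]] = []
    for e in prefix:
        if e.eid in xp_ids:
            a, b = ("sub", e.eid, 0), ("sub", e.eid, 1)
            flow_edges.append((e.u, a))
            backrefs.append(e)
            flow_edges.append((b, e.v))
            backrefs.append(e)
            middles.append((a, b))
        else:
            flow_edges.append((e.u, e.v))
            backrefs.append(e)
    best: list[Edge] | None = None
    for mask in range(2 ** (len(middles) - 1)):
        bits = [0] + [(mask >> j) & 1 for j in range(len(middles) - 1)]
        sources: set[Hashable] = set()
        sinks: set[Hashable] = set()
        for (a, b), bit in zip(middles, bits):
            if bit == 0:
                sources.add(a)
                sinks.add(b)
            else:
                sources.add(b)
                sinks.add(a)
        limit = target if best is None else len(best) - 1
        if limit < 0:
            break
        cut = min_edge_cut(flow_edges, sources, sinks, limit)
        if cut is None:
            continue
        mapped: dict[int, Edge] = {}
        for idx in cut:
            mapped[backrefs[idx].eid] = backrefs[idx]
        cand = [mapped[eid] for eid in sorted(mapped)]
        if best is None or len(cand) < len(best):
            best = cand
    if best is not None:
        assert _is_bipartite(prefix, {e.eid for e in best})
    return best


def edge_bipartization(g: SignedGraph | BipartizationInstance,
                       budget: int | None = None) -> set[int] | None:
    """Minimum set of edge ids whose removal makes the graph bipartite.

    Edge signs are ignored.  Self-loops are unconditionally part of any
    solution.  With ``budget`` given, returns ``None`` as soon as the
    optimum provably exceeds it.
    """
    if isinstance(g, BipartizationInstance):
        if budget is None:
            budget = g.budget
        g = g.graph
    forced = {e.eid for e in g.edges() if e.is_loop}
    edges = sorted((e for e in g.edges() if not e.is_loop),
                   key=lambda e: (str(e.u), str(e.v), e.eid))
    if budget is not None and len(forced) > budget:
        return None
    x: list[Edge] = []
    prefix: list[Edge] = []
    for e in edges:
        prefix.append(e)
        if _is_bipartite(prefix, {d.eid for d in x}):
            continue
        xprime = x + [e]
        y = compress(prefix, xprime)
        x = y if y is not None else xprime
        if budget is not None and len(forced) + len(x) > budget:
            return None
    return forced | {d.eid for d in x}


def two_coloring_from_removal(g: SignedGraph, removed: set[int],
                              ) -> dict[Hashable, int]:
    """Proper 2-coloring (sides 0/1) of ``g`` minus the removed edges.

    Each connected component is rooted at its smallest vertex id, which
    gets side 0.  Raises if an odd cycle survives.
    """
    side: dict[Hashable, int] = {}
    for start in g.vertices():
        if start in side:
            continue
        side[start] = 0
        q = deque([start])
        while q:
            x = q.popleft()
            for e in g.incident(x):
                if e.eid in removed:
                    continue
                if e.is_loop:
                    raise ValueError("self-loop survived edge removal")
                y = e.other(x)
                if y not in side:
                    side[y] = 1 - side[x]
                    q.append(y)
                elif side[y] == side[x]:
                    raise ValueError(
                        "removal set does not bipartize the graph")
    return side


# ---------------------------------------------------------------------------
# full chain on a signed graph


def solve_line_index(g: SignedGraph, k: int | None = None,
                     ) -> tuple[int, dict[Hashable, Color]] | None:
    """Exact line index of a signed graph with fixed resolved vertices.

    Runs the full transformation chain and maps the bipartition back to
    red/green labels.  With a budget ``k``, returns ``None`` when the
    line index exceeds it.
    """
    if g.num_vertices == 0:
        return 0, {}
    gneg = to_all_negative(g)
    gm, info = merge_and_guard(gneg, k)
    inst = negate_weights(gm)
    removal = edge_bipartization(inst.graph, budget=k)
    if removal is None:
        return None
    guard_hits = set(info.guard_eids) & removal
    assert not guard_hits, "guard edges must never be removed within budget"
    sides = two_coloring_from_removal(inst.graph, removal)
    if info.red_node is not None:
        red_side = sides[info.red_node]
        if info.green_node is not None:
            assert sides[info.green_node] != red_side
    elif info.green_node is not None:
        red_side = 1 - sides[info.green_node]
    else:
        red_side = 0
    colors: dict[Hashable, Color] = {}
    for v in g.vertices():
        own = g.color(v)
        if own.is_resolved:
            colors[v] = own
            continue
        colors[v] = Color.RED if sides[v] == red_side else Color.GREEN
    # the removal set corresponds one-to-one to frustrated original edges
    value = len(removal)
    return value, colors
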