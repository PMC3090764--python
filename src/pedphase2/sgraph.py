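"""Signed multigraph container shared by the whole phasing pipeline.

A pedigree with two biallelic sites per member is modelled as a *signed
graph*: vertices are labelled members (red = homozygous with opposite
values at the two sites, green = homozygous with equal values, grey =
doubly heterozygous and not yet phased), a positive edge says "same
label once resolved, else one recombination", a negative edge says
"different labels, else one recombination".  Parallel edges are
meaningful (several trios can constrain the same couple), so the
container is a true multigraph with stable integer edge ids and
per-edge provenance that survives copies, merges and the later
transformation to an unsigned bipartization instance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Any, Hashable, Iterator

POS = 1
NEG = -1


class Color(str, Enum):
    """Vertex label: red/green are resolved phases, grey is undecided."""

    RED = "red"
    GREEN = "green"
    GREY = "grey"

    @property
    def is_resolved(self) -> bool:
        return self is not Color.GREY


def opposite(color: Color) -> Color:
    if color is Color.RED:
        return Color.GREEN
    if color is Color.GREEN:
        return Color.RED
    raise ValueError("grey has no opposite label")


@dataclass(frozen=True)
class Edge:
    """A signed edge.  ``provenance`` records where it came from.

    Provenance tags used by the pipeline:

    * ``("pos", parent, child)``    parent-child transmission constraint
    * ``("neg", father, mother, child)``  trio with an unlabeled child
    * ``("half", eid)``             one half of a subdivided positive edge
    * ``("guard", i)``              supernode guard edge
    * ``("r7-2d", p1, p2)``         positive edge replacing a grey
                                    degree-2 vertex with two negative edges
    """

    eid: int
    u: Hashable
    v: Hashable
    sign: int
    provenance: tuple | None = None

    def other(self, vertex: Hashable) -> Hashable:
        if vertex == self.u:
            return self.v
        if vertex == self.v:
            return self.u
        raise KeyError(f"{vertex!r} is not an endpoint of edge {self.eid}")

    @property
    def is_loop(self) -> bool:
        return self.u == self.v


def _vkey(v: Hashable) -> str:
    return str(v)


class SignedGraph:
    """Mutable signed multigraph with colored vertices.

    Iteration orders (vertices by string key, edges by id) are
    deterministic so that every downstream algorithm is reproducible.
    """

    def __init__(self) -> None:
        self._color: dict[Hashable, Color] = {}
        self._inc: dict[Hashable, set[int]] = {}
        self._edge: dict[int, Edge] = {}
        self._next_eid = 0

    # -- vertices -----------------------------------------------------

    def add_vertex(self, v: Hashable, color: Color = Color.GREY) -> None:
        if v in self._color:
            raise ValueError(f"duplicate vertex {v!r}")
        self._color[v] = color
        self._inc[v] = set()

    def has_vertex(self, v: Hashable) -> bool:
        return v in self._color

    def color(self, v: Hashable) -> Color:
        return self._color[v]

    def set_color(self, v: Hashable, color: Color) -> None:
        if v not in self._color:
            raise KeyError(v)
        self._color[v] = color

    def vertices(self) -> list[Hashable]:
        return sorted(self._color, key=_vkey)

    def remove_vertex(self, v: Hashable) -> list[Edge]:
        """Delete ``v`` and all incident edges; returns the removed edges."""
        removed = [self._edge[eid] for eid in sorted(self._inc[v])]
        for edge in removed:
            self.remove_edge(edge.eid)
        del self._inc[v]
        del self._color[v]
        return removed

    # -- edges --------------------------------------------------------

    def add_edge(
        self,
        u: Hashable,
        v: Hashable,
        sign: int,
        provenance: tuple | None = None,
        eid: int | None = None,
    ) -> int:
        if sign not in (POS, NEG):
            raise ValueError(f"sign must be +1 or -1, got {sign}")
        if u not in self._color or v not in self._color:
            raise KeyError("both endpoints must exist before adding an edge")
        if eid is None:
            eid = self._next_eid
        elif eid in self._edge:
            raise ValueError(f"duplicate edge id {eid}")
        self._next_eid = max(self._next_eid, eid + 1)
        self._edge[eid] = Edge(eid, u, v, sign, provenance)
        self._inc[u].add(eid)
        self._inc[v].add(eid)
        return eid

    def edge(self, eid: int) -> Edge:
        return self._edge[eid]

    def has_edge(self, eid: int) -> bool:
        return eid in self._edge

    def edges(self) -> list[Edge]:
        return [self._edge[eid] for eid in sorted(self._edge)]

    def remove_edge(self, eid: int) -> Edge:
        edge = self._edge.pop(eid)
        self._inc[edge.u].discard(eid)
        self._inc[edge.v].discard(eid)
        return edge

    def rehome_edge(self, eid: int, old: Hashable, new: Hashable) -> Edge:
        """Move one endpoint of an edge (used when merging vertices)."""
        edge = self._edge[eid]
        if old not in (edge.u, edge.v):
            raise KeyError(f"{old!r} is not an endpoint of edge {eid}")
        u = new if edge.u == old else edge.u
        v = new if edge.v == old else edge.v
        self._inc[edge.u].discard(eid)
        self._inc[edge.v].discard(eid)
        moved = replace(edge, u=u, v=v)
        self._edge[eid] = moved
        self._inc[u].add(eid)
        self._inc[v].add(eid)
        return moved

    # -- queries ------------------------------------------------------

    def incident(self, v: Hashable) -> list[Edge]:
        return [self._edge[eid] for eid in sorted(self._inc[v])]

    def degree(self, v: Hashable) -> int:
        # a self-loop contributes 2, the usual multigraph convention
        return sum(2 if self._edge[eid].is_loop else 1 for eid in self._inc[v])

    def neighbors(self, v: Hashable) -> list[Hashable]:
        seen = {self._edge[eid].other(v) for eid in self._inc[v]
                if not self._edge[eid].is_loop}
        return sorted(seen, key=_vkey)

    @property
    def num_vertices(self) -> int:
        return len(self._color)

    @property
    def num_edges(self) -> int:
        return len(self._edge)

    def count_edges(self, sign: int) -> int:
        return sum(1 for e in self._edge.values() if e.sign == sign)

    def grey_vertices(self) -> list[Hashable]:
        return [v for v in self.vertices() if self._color[v] is Color.GREY]

    def __contains__(self, v: Hashable) -> bool:
        return v in self._color

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"SignedGraph({self.num_vertices} vertices, "
                f"{self.count_edges(POS)}+ / {self.count_edges(NEG)}- edges)")

    # -- copies and export --------------------------------------------

    def copy(self) -> "SignedGraph":
        g = SignedGraph()
        g._color = dict(self._color)
        g._inc = {v: set(s) for v, s in self._inc.items()}
        g._edge = dict(self._edge)
        g._next_eid = self._next_eid
        return g

    def to_networkx(self):
        """Export to a ``networkx.MultiGraph`` (colors and signs as attributes)."""
        import networkx as nx

        g = nx.MultiGraph()
        for v in self.vertices():
            g.add_node(str(v), color=self._color[v].value)
        for e in self.edges():
            g.add_edge(str(e.u), str(e.v), key=e.eid,
                       sign="pos" if e.sign == POS else "neg",
                       provenance=repr(e.provenance))
        return g
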