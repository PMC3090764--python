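"""Independent brute-force references.

These enumerate solution spaces directly and deliberately share no code
with the production pipeline (reduction, compression, replay): they are
the ground truth the pipeline is tested against on small instances.
Size guards fail loudly rather than silently truncating.
"""

from __future__ import annotations

from itertools import product
from typing import Hashable

from .pedio import Genotype2, Hap, Pedigree
from .sgraph import NEG, POS, Color, SignedGraph

MAX_GREY = 24
MAX_VERTICES = 24
MAX_MEMBERS = 12


class OracleSizeError(ValueError):
    """Instance too large for exhaustive enumeration."""


def line_index_bruteforce(g: SignedGraph,
                          ) -> tuple[int, dict[Hashable, Color]]:
    """Exact line index by enumerating all colorings of the grey
    vertices (resolved vertices keep their colors)."""
    greys = g.grey_vertices()
    if len(greys) > MAX_GREY:
        raise OracleSizeError(f"{len(greys)} grey vertices > {MAX_GREY}")
    edges = [(e.u, e.v, e.sign) for e in g.edges()]
    fixed = {v: g.color(v) for v in g.vertices() if g.color(v).is_resolved}
    best: int | None = None
    best_assign: dict[Hashable, Color] = {}
    for combo in product((Color.RED, Color.GREEN), repeat=len(greys)):
        colors = dict(fixed)
        colors.update(zip(greys, combo))
        cost = 0
        for u, v, sign in edges:
            same = colors[u] is colors[v]
            cost += (sign == POS and not same) or (sign == NEG and same)
        if best is None or cost < best:
            best, best_assign = cost, colors
    assert best is not None or not edges
    if best is None:  # vertex-free graph
        return 0, {}
    return best, best_assign


def bipartization_bruteforce(g: SignedGraph) -> set[int]:
    """Minimum edge-removal set making the graph bipartite, by
    enumerating all 2-colorings (signs are ignored)."""
    verts = g.vertices()
    if len(verts) > MAX_VERTICES:
        raise OracleSizeError(f"{len(verts)} vertices > {MAX_VERTICES}")
    edges = g.edges()
    if not verts:
        return set()
    best: set[int] | None = None
    # fix the first vertex's side: removal sets are symmetric under swap
    for combo in product((0, 1), repeat=len(verts) - 1):
        side = dict(zip(verts, (0,) + combo))
        mono = {e.eid for e in edges if side[e.u] == side[e.v]}
        if best is None or len(mono) < len(best):
            best = mono
    return best if best is not None else set()


def _pair_options(g: Genotype2) -> list[tuple[Hap, Hap]]:
    def alleles(code: int) -> tuple[int, int]:
        return {0: (0, 0), 1: (1, 1), 2: (0, 1)}[code]

    if g.site1 == 2 and g.site2 == 2:
        return [((0, 0), (1, 1)), ((0, 1), (1, 0))]
    a, b = alleles(g.site1), alleles(g.site2)
    return [((a[0], b[0]), (a[1], b[1]))]


def _tcost(pair: tuple[Hap, Hap], hap: Hap) -> int | None:
    a, b = pair
    if hap in (a, b):
        return 0
    if hap in ((a[0], b[1]), (b[0], a[1])):
        return 1
    return None


def mrhc_bruteforce(pedigree: Pedigree) -> int:
    """Minimum recombination count by enumerating every phase choice.

    Doubly heterozygous members contribute a binary choice
    ({00,11} versus {01,10}); all other members are forced.  Each trio
    then costs the cheaper of the two parent assignments of the child's
    haplotypes (infeasible assignments are excluded).
    """
    if pedigree.n > MAX_MEMBERS:
        raise OracleSizeError(f"{pedigree.n} members > {MAX_MEMBERS}")
    ids = pedigree.member_ids()
    options = {mid: _pair_options(pedigree.members[mid].genotype)
               for mid in ids}
    free = [mid for mid in ids if len(options[mid]) > 1]
    trios = pedigree.trios
    best: int | None = None
    for combo in product(range(2), repeat=len(free)):
        pairs = {mid: options[mid][0] for mid in ids}
        for mid, choice in zip(free, combo):
            pairs[mid] = options[mid][choice]
        total = 0
        for father, mother, child in trios:
            a, b = pairs[child]
            costs = []
            for hf, hm in ((a, b), (b, a)):
                cf = _tcost(pairs[father], hf)
                cm = _tcost(pairs[mother], hm)
                if cf is not None and cm is not None:
                    costs.append(cf + cm)
            if not costs:
                total = None  # this phase choice is infeasible
                break
            total += min(costs)
        if total is not None and (best is None or total < best):
            best = total
    if best is None:
        raise ValueError("no feasible haplotype configuration "
                         "(pedigree should have failed Mendelian checks)")
    return best
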