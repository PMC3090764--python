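"""Build the signed pedigree graph from a two-site pedigree.

Members with both sites homozygous are labeled green (equal values) or
red (opposite values); doubly heterozygous members are grey; members
with exactly one heterozygous site are *unlabeled* and get no vertex.
A positive edge joins each labeled parent-child pair ("same label once
resolved, else one recombination in the parent's transmission"); a
negative edge joins the two labeled parents of an unlabeled child
("different labels, else one recombination in one parent of that
child").  The minimum number of recombination events over all phasings
equals the minimum, over red/green assignments to the grey vertices, of
the number of *frustrated* edges: positive edges across the partition
plus negative edges within a side (the frustration / line index of the
signed graph).

A doubly homozygous parent carries two identical haplotypes, so its
gamete is invariant under crossover: a grey child of such a parent has
its phase forced, at no cost, to the parent's label.  That forcing is
applied here (``propagate_resolved``) as part of construction.  It is
deliberately *not* chained through grey vertices that were themselves
colored by propagation: such a vertex holds two distinct haplotypes and
can transmit a recombinant, so its child's phase stays a genuine
cost-1 degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping

from .pedio import Genotype2, Pedigree, PedigreeError
from .sgraph import NEG, POS, Color, Edge, SignedGraph

UNLABELED = None


def label_member(g: Genotype2) -> Color | None:
    """Vertex label for a genotype; ``None`` for unlabeled members."""
    g.validate()
    het = (g.site1 == 2, g.site2 == 2)
    if all(het):
        return Color.GREY
    if any(het):
        return UNLABELED
    return Color.GREEN if g.site1 == g.site2 else Color.RED


def build_graph(pedigree: Pedigree) -> SignedGraph:
    """Construct the signed pedigree graph (with forced propagation applied).

    The result has at most ``n`` vertices and O(n) edges: one vertex per
    labeled member, one positive edge per labeled parent-child pair and
    one negative edge per trio whose parents are labeled but whose child
    is not.
    """
    g = SignedGraph()
    labels = {mid: label_member(m.genotype)
              for mid, m in pedigree.members.items()}
    for mid in pedigree.member_ids():
        if labels[mid] is not UNLABELED:
            g.add_vertex(mid, labels[mid])
    for father, mother, child in pedigree.trios:
        if labels[child] is not UNLABELED:
            if labels[father] is UNLABELED and labels[mother] is UNLABELED:
                _force_phase_from_unlabeled_parents(g, pedigree, labels,
                                                    father, mother, child)
            for parent in (father, mother):
                if labels[parent] is not UNLABELED:
                    g.add_edge(parent, child, POS, ("pos", parent, child))
        elif labels[father] is not UNLABELED and labels[mother] is not UNLABELED:
            g.add_edge(father, mother, NEG, ("neg", father, mother, child))
        else:
            _pinned_transmission_edge(g, pedigree, labels,
                                      father, mother, child)
    genotype_resolved = {mid for mid, lab in labels.items()
                         if lab is not UNLABELED and lab.is_resolved}
    propagate_resolved(g, sources=genotype_resolved)
    return g


def _unlabeled_haps(g: Genotype2) -> tuple[tuple[int, int], tuple[int, int]]:
    """(green-patterned, red-patterned) transmissible haplotype of a
    one-heterozygous-site member; the set is closed under crossover."""
    if g.site1 == 2:
        z = g.site2
        return (z, z), (1 - z, z)
    z = g.site1
    return (z, z), (z, 1 - z)


def _force_phase_from_unlabeled_parents(g: SignedGraph, pedigree: Pedigree,
                                        labels: dict, father: str,
                                        mother: str, child: str) -> None:
    """Hard phase constraint on a grey child of two unlabeled parents.

    Each unlabeled parent can transmit exactly one equal-allele and one
    opposite-allele haplotype, whatever crossovers happen.  The child's
    green phase {00,11} is feasible only if the parents' equal-allele
    haplotypes differ, the red phase {01,10} only if their
    opposite-allele haplotypes differ.  When only one phase is feasible
    the child's color is forced outright (no recombination can buy the
    other phase), which is recorded by resolving its vertex here.
    """
    if labels[child] is not Color.GREY:
        return  # doubly homozygous child: its pair is already unique
    gf, gm = (_unlabeled_haps(pedigree.members[p].genotype)
              for p in (father, mother))
    green_ok = gf[0] != gm[0]
    red_ok = gf[1] != gm[1]
    if green_ok and red_ok:
        return
    if not (green_ok or red_ok):
        raise PedigreeError(
            f"trio ({father},{mother})->{child}: no feasible phase "
            "(genotypes are inconsistent)")
    g.set_color(child, Color.GREEN if green_ok else Color.RED)


def _pattern(hap: tuple[int, int]) -> Color:
    return Color.GREEN if hap[0] == hap[1] else Color.RED


def _pinned_transmission_edge(g: SignedGraph, pedigree: Pedigree,
                              labels: dict, father: str, mother: str,
                              child: str) -> None:
    """Constraint for a trio with an unlabeled child and exactly one
    labeled (grey) parent.

    The unlabeled co-parent w carries one heterozygous site; whichever
    way w recombines, its transmissible haplotypes are its own two.  If
    w's heterozygous site is the child's *homozygous* site, only one of
    them fits the child, so the grey parent u must transmit the
    complementary haplotype cj exactly: one recombination occurs in u
    unless u resolves to cj's pattern (green for equal alleles, red for
    opposite).  The constraint is recorded as a resolved vertex for the
    unlabeled child (keeping one vertex per member at most) joined to u
    by a positive edge.  If u is doubly homozygous the per-site
    Mendelian check already forces a match and nothing is added; if w
    is heterozygous at the child's heterozygous site both of w's
    haplotypes fit and the trio is unconstrained, as are trios with no
    labeled parent at all.
    """
    lab_f, lab_m = labels[father], labels[mother]
    if (lab_f is UNLABELED) == (lab_m is UNLABELED):
        return  # no labeled parent: nothing detectable
    u, w = (father, mother) if lab_f is not UNLABELED else (mother, father)
    if labels[u] is not Color.GREY:
        return  # doubly homozygous parent: match guaranteed by Mendelian rules
    gc = pedigree.members[child].genotype
    gw = pedigree.members[w].genotype
    t = 0 if gc.site1 == 2 else 1  # the child's heterozygous site
    o = 1 - t
    if gw[t] == 2:
        return  # w heterozygous at the same site: both haplotypes fit
    cj = [0, 0]
    cj[t] = 1 - gw[t]
    cj[o] = gc[o]
    g.add_vertex(child, _pattern((cj[0], cj[1])))
    g.add_edge(child, u, POS, ("pos-constraint", u, child))


def propagate_resolved(g: SignedGraph,
                       sources: set | None = None) -> SignedGraph:
    """Force the phase of grey children of resolved parents, in place.

    Only doubly homozygous parents have crossover-invariant
    transmissions, so only they may act as sources; ``build_graph``
    passes that set explicitly.  By default every vertex resolved on
    entry is a source.  Children colored here never become sources
    themselves: they hold two distinct haplotypes and can transmit a
    recombinant, so their children's phases remain cost-1 choices.
    """
    if sources is None:
        sources = {v for v in g.vertices() if g.color(v).is_resolved}
    forced: dict[Hashable, Color] = {}
    for edge in g.edges():
        if edge.sign != POS or not edge.provenance or edge.provenance[0] != "pos":
            continue
        parent, child = edge.provenance[1], edge.provenance[2]
        if parent not in sources or not g.has_vertex(child):
            continue
        if g.color(child) is not Color.GREY:
            continue
        want = g.color(parent)
        if forced.setdefault(child, want) is not want:
            raise PedigreeError(
                f"member {child} forced to two different phases by its "
                "resolved parents; genotypes are inconsistent")
    for child, color in forced.items():
        g.set_color(child, color)
    return g


@dataclass
class LineIndexValue:
    """Frustration of one red/green assignment: the partition, the
    frustrated edge set and its size (= recombination count)."""

    value: int
    frustrated: list[Edge]
    partition: dict[Hashable, str]  # vertex -> "V1" (red side) / "V2"


def line_index_of_labeling(g: SignedGraph,
                           colors: Mapping[Hashable, Color] | None = None,
                           ) -> LineIndexValue:
    """Count frustrated edges under a full labeling.

    ``colors`` supplies labels for grey vertices (and may restate
    resolved ones, which must match).  Frustrated = positive edge with
    differently-colored endpoints, or negative edge with same-colored
    endpoints; a negative self-loop is always frustrated.
    """
    colors = colors or {}

    def full(v: Hashable) -> Color:
        own = g.color(v)
        if own.is_resolved:
            got = colors.get(v, own)
            if got is not own:
                raise ValueError(f"vertex {v} is resolved {own.value}, "
                                 f"labeling says {got.value}")
            return own
        try:
            c = colors[v]
        except KeyError:
            raise ValueError(f"grey vertex {v} has no assigned label") from None
        if not c.is_resolved:
            raise ValueError(f"vertex {v} assigned grey")
        return c

    frustrated = []
    partition = {v: ("V1" if full(v) is Color.RED else "V2")
                 for v in g.vertices()}
    for e in g.edges():
        same = partition[e.u] == partition[e.v]
        if (e.sign == POS and not same) or (e.sign == NEG and same):
            frustrated.append(e)
    return LineIndexValue(len(frustrated), frustrated, partition)
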