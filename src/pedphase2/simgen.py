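"""Random complex looped pedigrees and gene-dropped two-site genotypes.

The generator emulates highly connected, cyclic pedigrees of the kind
found in species with overlapping generations and repeated matings
(goats, fish, horses): every mating picks an existing member as one
parent, and with probability ``loop_rate`` the second parent is also an
existing member — possibly a descendant of the first — which closes a
cycle; otherwise a fresh external founder joins.  Members therefore
accumulate many spouses, including their own children or
grandchildren.

Genotypes come from gene dropping: founders draw two haplotypes from
``founder_freqs`` over {00, 01, 10, 11}; each transmission copies a
uniformly chosen parental haplotype, replaced by the between-sites
recombinant either independently with probability ``recomb_rate`` or
at exactly ``planted_events`` uniformly chosen transmissions.  The
resulting genotypes are Mendelian-consistent by construction and the
planted event list upper-bounds the minimum recombination count.

Defaults (two children per mating on average, loop rate 0.3, uniform
founder haplotypes, no recombination) make roughly half of all members
labeled, matching the initial-graph sizes used in the reduction-rule
benchmark (about n/2 vertices, 0.35 n positive and 0.09 n negative
edges at n = 1000).

``random_signed_graph`` and ``random_multigraph`` generate the small
abstract instances used to exercise the graph algorithms directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .pedio import Genotype2, Hap, Member, Pedigree
from .sgraph import NEG, POS, Color, SignedGraph

HAPLOTYPES: tuple[Hap, ...] = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass
class SimParams:
    """Simulation settings; ``seed`` fully determines the output."""

    n_members: int
    mean_children: float = 2.0
    loop_rate: float = 0.3
    founder_freqs: tuple[float, float, float, float] = (.25, .25, .25, .25)
    recomb_rate: float = 0.0
    planted_events: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 3:
            raise ValueError("need at least 3 members (one trio)")
        if abs(sum(self.founder_freqs) - 1.0) > 1e-9:
            raise ValueError("founder haplotype frequencies must sum to 1")
        if not 0.0 <= self.loop_rate <= 1.0:
            raise ValueError("loop_rate must be a probability")


@dataclass
class SimTruth:
    """Ground truth of one simulation."""

    haplotypes: dict[str, tuple[Hap, Hap]]
    events: list[tuple[str, str]]  # (child, transmitting parent)
    params: SimParams


Structure = list[tuple[str, str | None, str | None]]


def _mid(i: int) -> str:
    return f"m{i:05d}"


def generate_pedigree(params: SimParams,
                      rng: np.random.Generator | None = None) -> Structure:
    """Random connected pedigree structure (ids with parent links, in
    topological order; genotypes are added by :func:`drop_genes`)."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    n = params.n_members
    members: Structure = [(_mid(0), None, None), (_mid(1), None, None)]
    couples: list[tuple[str, str]] = []
    looped = False

    def fresh(father: str | None, mother: str | None) -> str:
        mid = _mid(len(members))
        members.append((mid, father, mother))
        return mid

    def random_member() -> str:
        return members[int(rng.integers(len(members)))][0]

    while len(members) < n:
        force_loop = (params.loop_rate > 0 and not looped
                      and len(members) >= n - 1)
        if not couples:
            father, mother = _mid(0), _mid(1)
        elif force_loop or rng.random() < params.loop_rate:
            # mate two existing (already connected) members: closes a cycle
            father = random_member()
            others = [m for m, _, _ in members if m != father]
            mother = others[int(rng.integers(len(others)))]
            looped = True
        elif len(members) <= n - 2:
            father, mother = random_member(), fresh(None, None)
        else:
            # no room for a new external spouse: extend an existing family
            father, mother = couples[int(rng.integers(len(couples)))]
        couples.append((father, mother))
        n_children = 1 + int(rng.poisson(max(params.mean_children - 1, 0)))
        for _ in range(n_children):
            if len(members) >= n:
                break
            if params.loop_rate > 0 and not looped and len(members) >= n - 1:
                break  # keep one slot so a cycle-closing mating still fits
            fresh(father, mother)
    return members


def drop_genes(structure: Structure, params: SimParams,
               rng: np.random.Generator | None = None,
               ) -> tuple[Pedigree, SimTruth]:
    """Assign haplotypes down the pedigree and derive genotypes."""
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    transmissions = [(child, parent)
                     for child, father, mother in structure
                     if father is not None
                     for parent in (father, mother)]
    recomb_at: set[int] = set()
    if params.planted_events is not None:
        if params.planted_events > len(transmissions):
            raise ValueError(
                f"cannot plant {params.planted_events} events in "
                f"{len(transmissions)} transmissions")
        recomb_at = set(map(int, rng.choice(
            len(transmissions), size=params.planted_events, replace=False)))

    haps: dict[str, tuple[Hap, Hap]] = {}
    events: list[tuple[str, str]] = []
    t_index = 0
    for child, father, mother in structure:
        if father is None:
            idx = rng.choice(len(HAPLOTYPES), size=2, p=params.founder_freqs)
            haps[child] = (HAPLOTYPES[int(idx[0])], HAPLOTYPES[int(idx[1])])
            continue
        received = []
        for parent in (father, mother):
            a, b = haps[parent]
            first, second = (a, b) if rng.integers(2) == 0 else (b, a)
            if params.planted_events is not None:
                recombine = t_index in recomb_at
            else:
                recombine = rng.random() < params.recomb_rate
            if recombine:
                received.append((first[0], second[1]))
                events.append((child, parent))
            else:
                received.append(first)
            t_index += 1
        haps[child] = (received[0], received[1])

    def code(x: int, y: int) -> int:
        return x if x == y else 2

    members = []
    for child, father, mother in structure:
        h1, h2 = haps[child]
        members.append(Member(
            member_id=child, father_id=father, mother_id=mother,
            genotype=Genotype2(code(h1[0], h2[0]), code(h1[1], h2[1])),
        ))
    return Pedigree(members), SimTruth(haps, sorted(events), params)


def simulate(params: SimParams) -> tuple[Pedigree, SimTruth]:
    """Structure + gene drop under a single seeded RNG stream."""
    rng = np.random.default_rng(params.seed)
    structure = generate_pedigree(params, rng)
    return drop_genes(structure, params, rng)


def write_ped(pedigree: Pedigree, path, family: str = "F1") -> None:
    """Write a pedigree in the two-site PED dialect read by ``pedio``."""
    rows = []
    allele = {0: ("1", "1"), 1: ("2", "2"), 2: ("1", "2")}
    for mid in pedigree.member_ids():
        m = pedigree.members[mid]
        g = m.genotype
        rows.append(" ".join([
            m.family_id or family, mid,
            m.father_id or "0", m.mother_id or "0", m.sex or "0",
            *allele[g.site1], *allele[g.site2]]))
    from pathlib import Path
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# abstract graph instances for direct algorithm tests


def random_signed_graph(rng: np.random.Generator, max_vertices: int = 10,
                        max_edges: int = 14,
                        grey_fraction: float = 0.6) -> SignedGraph:
    """Random small signed multigraph with mixed vertex colors."""
    n = int(rng.integers(2, max_vertices + 1))
    g = SignedGraph()
    for i in range(n):
        r = rng.random()
        if r < grey_fraction:
            color = Color.GREY
        elif r < grey_fraction + (1 - grey_fraction) / 2:
            color = Color.RED
        else:
            color = Color.GREEN
        g.add_vertex(i, color)
    m = int(rng.integers(0, max_edges + 1))
    for _ in range(m):
        u, v = map(int, rng.choice(n, size=2, replace=False))
        sign = POS if rng.random() < 0.5 else NEG
        g.add_edge(u, v, sign)
    return g


def random_multigraph(rng: np.random.Generator, max_vertices: int = 10,
                      max_edges: int = 16) -> SignedGraph:
    """Random unsigned multigraph (edge signs all positive, colors grey)."""
    n = int(rng.integers(2, max_vertices + 1))
    g = SignedGraph()
    for i in range(n):
        g.add_vertex(i, Color.GREY)
    m = int(rng.integers(0, max_edges + 1))
    for _ in range(m):
        u, v = map(int, rng.choice(n, size=2, replace=False))
        g.add_edge(u, v, POS)
    return g
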