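"""End-to-end phasing: decision and minimization runs plus haplotype
reconstruction.

``minimize`` finds the smallest number of recombination events k* that
explains the pedigree, together with a witness haplotype configuration;
``decide`` answers whether k events suffice.  Both run the same
pipeline: signed-graph construction, data reduction, transformation to
Bipartization by Edge Removal, iterative compression, then replay of
the reduction trace to recover a full red/green labeling and finally
concrete haplotypes with localized events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

from .bipartization import solve_line_index
from .graph_build import build_graph, label_member, line_index_of_labeling
from .pedio import (Genotype2, Hap, HaplotypeConfiguration, Member, Pedigree,
                    PedigreeError, forced_pair, haplotype_pair_options)
from .reduction import reduce_to_fixpoint, replay_trace
from .sgraph import Color, Edge


class PhasingError(RuntimeError):
    """Internal inconsistency between labeling and genotypes."""


@dataclass
class SolveResult:
    k_star: int
    config: HaplotypeConfiguration
    colors: dict[Hashable, Color]
    frustrated: list[Edge]
    stats: dict = field(default_factory=dict)


def transmission_cost(pair: tuple[Hap, Hap], hap: Hap) -> int | None:
    """Events needed for a parent with haplotypes ``pair`` to transmit
    ``hap``: 0 if parental, 1 if a between-sites recombinant, None if
    impossible."""
    a, b = pair
    if hap == a or hap == b:
        return 0
    if hap == (a[0], b[1]) or hap == (b[0], a[1]):
        return 1
    return None


def _unordered_pairs(pedigree: Pedigree,
                     colors: dict[Hashable, Color],
                     ) -> dict[str, tuple[Hap, Hap]]:
    pairs: dict[str, tuple[Hap, Hap]] = {}
    for mid, member in pedigree.members.items():
        fixed = forced_pair(member.genotype)
        if fixed is not None:
            pairs[mid] = fixed
            continue
        color = colors.get(mid)
        if color is None or not color.is_resolved:
            raise PhasingError(f"grey member {mid} has no resolved label")
        pairs[mid] = ((0, 0), (1, 1)) if color is Color.GREEN \
            else ((0, 1), (1, 0))
    return pairs


def _assign_trio(pair_f: tuple[Hap, Hap], pair_m: tuple[Hap, Hap],
                 child_pair: tuple[Hap, Hap],
                 ) -> tuple[Hap, Hap, int, int]:
    """Choose which child haplotype is paternal.

    Returns (paternal hap, maternal hap, father events, mother events),
    minimizing total events; ties prefer attributing the event to the
    father (the convention used for trio-caused recombinations), then
    the lexicographically first assignment.
    """
    a, b = child_pair
    options = []
    for hf, hm in ((a, b), (b, a)):
        cf = transmission_cost(pair_f, hf)
        cm = transmission_cost(pair_m, hm)
        if cf is None or cm is None:
            continue
        options.append((cf + cm, -cf, (hf, hm, cf, cm)))
    if not options:
        raise PhasingError(
            "child haplotypes cannot be produced by the parents")
    options.sort(key=lambda t: (t[0], t[1]))
    hf, hm, cf, cm = options[0][2]
    return hf, hm, cf, cm


def labels_to_haplotypes(pedigree: Pedigree,
                         colors: dict[Hashable, Color],
                         ) -> HaplotypeConfiguration:
    """Concrete haplotypes from a full red/green labeling.

    Grey members take {00,11} (green) or {01,10} (red); everyone else
    has a unique unordered pair.  Within each trio the child's pair is
    oriented so that h1 is paternal, choosing the assignment with the
    fewest events; founders are ordered lexicographically.
    """
    for mid, member in pedigree.members.items():
        lab = label_member(member.genotype)
        if lab is not None and lab.is_resolved:
            got = colors.get(mid, lab)
            if got is not lab:
                raise PhasingError(
                    f"resolved member {mid} relabeled {got.value}")
    pairs = _unordered_pairs(pedigree, colors)
    phased: dict[str, tuple[Hap, Hap]] = {}
    events: list[tuple[str, str]] = []
    origins: dict[str, dict[str, str]] = {}
    chosen: dict[str, tuple] = {}
    for father, mother, child in pedigree.trios:
        hf, hm, cf, cm = _assign_trio(pairs[father], pairs[mother],
                                      pairs[child])
        phased[child] = (hf, hm)
        chosen[child] = (father, mother, hf, hm, cf, cm)
        events.extend([(child, father)] * cf + [(child, mother)] * cm)
    for mid in pedigree.member_ids():
        if mid not in phased:
            phased[mid] = tuple(sorted(pairs[mid]))  # type: ignore[assignment]
    for child, (father, mother, hf, hm, cf, cm) in chosen.items():
        origins[child] = {
            "father": _origin_of(phased[father], hf, cf),
            "mother": _origin_of(phased[mother], hm, cm),
        }
    return HaplotypeConfiguration(phased=phased, events=sorted(events),
                                  origins=origins)


def _origin_of(parent_ordered: tuple[Hap, Hap], hap: Hap, cost: int) -> str:
    if cost:
        return "recombinant"
    return "h1" if hap == parent_ordered[0] else "h2"


def count_recombinations(pedigree: Pedigree,
                         config: HaplotypeConfiguration,
                         ) -> tuple[int, list[tuple[str, str]]]:
    """Independently count events implied by a configuration.

    For every trio each transmitted haplotype costs 0 if parental and 1
    if recombinant, minimized over the two ways of assigning the
    child's haplotypes to the parents.  Errors if the configuration
    violates a genotype or an impossible transmission is required.
    """
    config.validate_against(pedigree)
    total = 0
    events: list[tuple[str, str]] = []
    for father, mother, child in pedigree.trios:
        _, _, cf, cm = _assign_trio(config.phased[father],
                                    config.phased[mother],
                                    config.phased[child])
        total += cf + cm
        events.extend([(child, father)] * cf + [(child, mother)] * cm)
    return total, sorted(events)


# ---------------------------------------------------------------------------
# pipeline


def _phase_from_colors(pedigree: Pedigree, g0, full_colors,
                       ) -> tuple[int, HaplotypeConfiguration, list[Edge]]:
    li = line_index_of_labeling(g0, full_colors)
    config = labels_to_haplotypes(pedigree, full_colors)
    return li.value, config, li.frustrated


def minimize(pedigree: Pedigree) -> SolveResult:
    """Smallest recombination count k* and a witness configuration."""
    g0 = build_graph(pedigree)
    red = reduce_to_fixpoint(g0)
    sol = solve_line_index(red.graph, None)
    assert sol is not None  # unbudgeted run always succeeds
    l_reduced, reduced_colors = sol
    full = replay_trace(red.trace, reduced_colors)
    k_star, config, frustrated = _phase_from_colors(pedigree, g0, full)
    if k_star != red.cost + l_reduced:
        raise PhasingError(
            f"bookkeeping mismatch: {k_star} != {red.cost} + {l_reduced}")
    stats = {
        "initial_vertices": g0.num_vertices,
        "initial_pos_edges": g0.count_edges(+1),
        "initial_neg_edges": g0.count_edges(-1),
        "reduced_vertices": red.graph.num_vertices,
        "reduced_pos_edges": red.graph.count_edges(+1),
        "reduced_neg_edges": red.graph.count_edges(-1),
        "reduction_cost": red.cost,
        "reduced_line_index": l_reduced,
    }
    return SolveResult(k_star, config, full, frustrated, stats)


def decide(pedigree: Pedigree, k: int,
           ) -> tuple[bool, HaplotypeConfiguration | None]:
    """Is there a haplotype configuration with at most ``k`` events?

    Returns (answer, witness-or-None); the witness has at most ``k``
    events.
    """
    if k < 0:
        raise ValueError("budget k must be non-negative")
    g0 = build_graph(pedigree)
    red = reduce_to_fixpoint(g0, k=k)
    if red.no_instance:
        return False, None
    sol = solve_line_index(red.graph, red.k)
    if sol is None:
        return False, None
    _, reduced_colors = sol
    full = replay_trace(red.trace, reduced_colors)
    total, config, _ = _phase_from_colors(pedigree, g0, full)
    if total > k:  # defensive; the budgeted run should have said no
        raise PhasingError("witness exceeds the budget")
    return True, config
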