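"""Two-site pedigree I/O and domain types.

Input is a LINKAGE/PED-style whitespace-separated text file with one
member per row::

    family  individual  father  mother  sex  a1 a2  b1 b2

where ``a1 a2`` are the two alleles at the first SNP site and ``b1 b2``
at the second, coded 1/2 (0 means missing, which is rejected: the
method assumes complete, error-free genotypes).  Father/mother ``0``
marks a founder or external parent.  The sex column is parsed but never
used for inheritance; parental roles come from the father/mother
columns, so the format also fits species where a member's "spouses" may
include its own descendants.

Each member carries a per-site genotype code: 0 (homozygous 0/0),
1 (homozygous 1/1) or 2 (heterozygous).  Exactly two sites are
supported; extending the constraint graph to more sites raises a
parity-consistency problem that this package deliberately does not
attempt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

Hap = tuple[int, int]  # one haplotype over the two sites


class PedigreeError(ValueError):
    """Base class for invalid pedigree input."""


class MissingDataError(PedigreeError):
    """Allele code 0 encountered: the model assumes complete data."""


class StructureError(PedigreeError):
    """Malformed rows, unknown parents, one-parent children, duplicates."""


class MendelianError(PedigreeError):
    """A trio violates Mendelian inheritance at one of the two sites."""


class Genotype2(NamedTuple):
    """Genotype codes at the two sites, each in {0, 1, 2}."""

    site1: int
    site2: int

    def validate(self) -> "Genotype2":
        if self.site1 not in (0, 1, 2) or self.site2 not in (0, 1, 2):
            raise PedigreeError(f"genotype codes must be 0/1/2, got {self}")
        return self


def _site_alleles(code: int) -> tuple[int, int]:
    return {0: (0, 0), 1: (1, 1), 2: (0, 1)}[code]


def haplotype_pair_options(g: Genotype2) -> list[tuple[Hap, Hap]]:
    """All unordered haplotype pairs consistent with a genotype.

    Doubly heterozygous members have two phase choices ({00,11} versus
    {01,10}); every other genotype determines its pair uniquely.
    """
    g.validate()
    if g.site1 == 2 and g.site2 == 2:
        return [((0, 0), (1, 1)), ((0, 1), (1, 0))]
    a = _site_alleles(g.site1)
    b = _site_alleles(g.site2)
    pair = tuple(sorted([(a[0], b[0]), (a[1], b[1])]))
    return [pair]  # type: ignore[list-item]


def forced_pair(g: Genotype2) -> tuple[Hap, Hap] | None:
    """The unique haplotype pair, or ``None`` for doubly heterozygous."""
    opts = haplotype_pair_options(g)
    return opts[0] if len(opts) == 1 else None


@dataclass(frozen=True)
class Member:
    member_id: str
    father_id: str | None
    mother_id: str | None
    genotype: Genotype2
    sex: str | None = None
    family_id: str | None = None

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise StructureError(
                f"member {self.member_id}: a child needs both parents "
                "(or neither, for a founder)")
        if self.member_id in (self.father_id, self.mother_id):
            raise StructureError(f"member {self.member_id} is its own parent")
        if self.father_id is not None and self.father_id == self.mother_id:
            raise StructureError(
                f"member {self.member_id}: father and mother must differ")
        self.genotype.validate()

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


class Pedigree:
    """A validated two-site pedigree; loops (multiple inheritance paths)
    are permitted."""

    def __init__(self, members: Iterable[Member]):
        self.members: dict[str, Member] = {}
        for m in members:
            if m.member_id in self.members:
                raise StructureError(f"duplicate member id {m.member_id!r}")
            self.members[m.member_id] = m
        self._validate_structure()
        self._validate_mendelian()

    # sequence of (father_id, mother_id, child_id), child-id sorted
    @property
    def trios(self) -> list[tuple[str, str, str]]:
        return [(m.father_id, m.mother_id, m.member_id)
                for mid, m in sorted(self.members.items())
                if m.father_id is not None]

    @property
    def n(self) -> int:
        return len(self.members)

    def member_ids(self) -> list[str]:
        return sorted(self.members)

    def _validate_structure(self) -> None:
        for m in self.members.values():
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in self.members:
                    raise StructureError(
                        f"member {m.member_id} references unknown parent {pid!r}")

    def _validate_mendelian(self) -> None:
        for father, mother, child in self.trios:
            gf = self.members[father].genotype
            gm = self.members[mother].genotype
            gc = self.members[child].genotype
            for site, (cf, cm, cc) in enumerate(zip(gf, gm, gc), start=1):
                fa = set(_site_alleles(cf))
                ma = set(_site_alleles(cm))
                c1, c2 = _site_alleles(cc)
                ok = any(x in fa and y in ma for x, y in ((c1, c2), (c2, c1)))
                if not ok:
                    raise MendelianError(
                        f"trio ({father},{mother})->{child} is Mendelian-"
                        f"inconsistent at site {site}")


@dataclass
class HaplotypeConfiguration:
    """Phased result: ordered haplotype pair per member plus the
    localized recombination events.

    ``phased[m] = (h1, h2)`` with h1 the paternal-origin haplotype where
    a parent exists (lexicographically smaller for founders); ``events``
    is a list of ``(child_id, parent_id)`` records, one per
    recombination; ``origins[child][role]`` says which parental
    haplotype ("h1"/"h2") or "recombinant" produced each transmitted
    haplotype.
    """

    phased: dict[str, tuple[Hap, Hap]]
    events: list[tuple[str, str]] = field(default_factory=list)
    origins: dict[str, dict[str, str]] = field(default_factory=dict)

    def validate_against(self, pedigree: Pedigree) -> None:
        for mid, member in pedigree.members.items():
            if mid not in self.phased:
                raise PedigreeError(f"member {mid} missing from configuration")
            pair = tuple(sorted(self.phased[mid]))
            if pair not in haplotype_pair_options(member.genotype):
                raise PedigreeError(
                    f"haplotypes of {mid} inconsistent with genotype "
                    f"{member.genotype}")
        trio_children = {c for _, _, c in pedigree.trios}
        for child, parent in self.events:
            if child not in trio_children:
                raise PedigreeError(
                    f"event references {child}, which has no recorded trio")
            m = pedigree.members[child]
            if parent not in (m.father_id, m.mother_id):
                raise PedigreeError(
                    f"event ({child},{parent}) does not match the child's trio")


# ---------------------------------------------------------------------------
# reading


def _genotype_from_alleles(a1: str, a2: str, where: str) -> int:
    codes = {a1, a2}
    if "0" in codes:
        raise MissingDataError(f"{where}: missing allele (code 0)")
    if not codes <= {"1", "2"}:
        raise PedigreeError(f"{where}: alleles must be coded 1/2, got {a1}/{a2}")
    if codes == {"1"}:
        return 0
    if codes == {"2"}:
        return 1
    return 2


def read_pedigree(path: str | Path) -> Pedigree:
    """Parse and fully validate a two-site PED file."""
    members = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 9:
            raise StructureError(
                f"{path}:{lineno}: expected 9 columns "
                "(family id father mother sex + 2 sites x 2 alleles), "
                f"got {len(cols)}")
        fam, mid, father, mother, sex = cols[:5]
        where = f"{path}:{lineno} (member {mid})"
        g = Genotype2(
            _genotype_from_alleles(cols[5], cols[6], where),
            _genotype_from_alleles(cols[7], cols[8], where),
        )
        members.append(Member(
            member_id=mid,
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
            genotype=g,
            sex=sex,
            family_id=fam,
        ))
    return Pedigree(members)


# ---------------------------------------------------------------------------
# writing results


def _hap_str(h: Hap) -> str:
    return f"{h[0]}{h[1]}"


def write_results(config: HaplotypeConfiguration, k_star: int,
                  path: str | Path) -> None:
    """Write the phased haplotypes as TSV plus a JSON events sidecar.

    The sidecar lands next to ``path`` with a ``.json`` suffix.  Output
    ordering is deterministic (member-id sort) and round-trips through
    :func:`read_results`.
    """
    path = Path(path)
    lines = ["member_id\th1\th2"]
    for mid in sorted(config.phased):
        h1, h2 = config.phased[mid]
        lines.append(f"{mid}\t{_hap_str(h1)}\t{_hap_str(h2)}")
    path.write_text("\n".join(lines) + "\n")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"k_star": k_star,
         "events": [list(ev) for ev in config.events]},
        indent=2) + "\n")


def read_results(path: str | Path) -> tuple[HaplotypeConfiguration, int]:
    """Inverse of :func:`write_results` (origins are not serialized)."""
    path = Path(path)
    phased: dict[str, tuple[Hap, Hap]] = {}
    rows = path.read_text().splitlines()
    for row in rows[1:]:
        if not row.strip():
            continue
        mid, h1, h2 = row.split("\t")
        phased[mid] = ((int(h1[0]), int(h1[1])), (int(h2[0]), int(h2[1])))
    meta = json.loads(path.with_suffix(".json").read_text())
    config = HaplotypeConfiguration(
        phased=phased,
        events=[tuple(ev) for ev in meta["events"]],
    )
    return config, int(meta["k_star"])


def write_graphml(graph, path: str | Path) -> None:
    """Export a signed pedigree graph to GraphML (colors, signs,
    provenance as attributes)."""
    import networkx as nx

    nx.write_graphml(graph.to_networkx(), str(path))
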