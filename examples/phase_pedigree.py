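"""Phase a small looped pedigree with the minimum number of recombinations.

Builds an eight-member pedigree in which three doubly heterozygous
members are pairwise co-parents of children with a single heterozygous
site.  Those children make their parents' phases *disagree* pairwise --
an odd cycle of constraints that no recombination-free configuration
can satisfy -- so the optimum is exactly one event.
"""

from pedphase2 import Genotype2, Member, Pedigree, count_recombinations, minimize

ped = Pedigree([
    Member("anna", None, None, Genotype2(2, 2)),
    Member("bert", None, None, Genotype2(2, 2)),
    Member("cara", None, None, Genotype2(2, 2)),
    Member("ab", "anna", "bert", Genotype2(0, 2)),
    Member("bc", "bert", "cara", Genotype2(0, 2)),
    Member("ca", "cara", "anna", Genotype2(0, 2)),
    Member("dave", None, None, Genotype2(0, 1)),
    Member("ad", "dave", "anna", Genotype2(2, 2)),
])

result = minimize(ped)
print(f"minimum recombination events k* = {result.k_star}")
for member_id in sorted(result.config.phased):
    h1, h2 = result.config.phased[member_id]
    print(f"  {member_id:>5}: h1={h1[0]}{h1[1]} h2={h2[0]}{h2[1]}")
for child, parent in result.config.events:
    print(f"  recombination in {parent}'s transmission to {child}")

# independent re-count from the haplotypes themselves
count, _ = count_recombinations(ped, result.config)
print(f"independent event count from the witness: {count}")
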