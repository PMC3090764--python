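# pedphase2

Exact minimum-recombinant haplotype phasing for **general pedigrees with
loops**, where every member is genotyped at **two biallelic SNP sites**.

## The problem

Genotypes are cheap; haplotypes — the allele sequence on each single
chromosome copy — are what genetic studies actually need. In a pedigree,
a child's two haplotypes come from its parents, one from each, except
where meiotic recombination splices a parent's two haplotypes into the
transmitted copy. The *minimum-recombinant haplotype configuration*
(MRHC) problem asks for haplotypes of **all** members, consistent with
every genotype, that minimize the total number of recombination events.
The problem is NP-hard already for two sites once pedigrees may contain
loops (inbreeding, intergenerational matings, members with many spouses
— common in goats, fish and horses), but it is fixed-parameter
tractable in the number of events `k`: this package solves it exactly in
`O(2^k · n²)`.

## The method

With two sites, each member's genotype `g_u ∈ {0,1,2}²` (0/1 homozygous,
2 heterozygous) labels it

* **green** — homozygous with equal values at the two sites,
* **red** — homozygous with opposite values,
* **grey** — heterozygous at both sites (phase unknown),
* *unlabeled* — heterozygous at exactly one site.

Phasing a grey member means deciding whether its haplotypes are
`{00,11}` (green) or `{01,10}` (red). A **signed pedigree graph** G
carries one vertex per member, a **positive edge** per labeled
parent–child pair ("same color, else one recombination") and a
**negative edge** between the labeled parents of an unlabeled child
("opposite colors, else one recombination"). Minimizing recombinations
is then computing the **line index** (frustration index) of G: the
minimum, over red/green assignments to the grey vertices, of positive
edges across the partition plus negative edges inside a side.

The solver pipeline:

1. **Data reduction** — degree-0/1 rules, resolved-pair edge rules,
   majority forcing, budget forcing, and a complete case analysis of
   degree-2 grey vertices shrink `(G, k)` to `(G', k')` with a
   replayable trace; on simulated 1000–10000-member pedigrees the rules
   remove ≈99.9% of vertices and edges.
2. **Bipartization by Edge Removal** — positive edges are subdivided
   into two negative halves (line index invariant), the red and green
   vertices are merged into two supernodes held apart by `k+1` parallel
   guard edges, and negating all weights turns frustrated edges into
   monochromatic ones: delete at most `k'` edges to make the graph
   bipartite.
3. **Iterative compression** — edges are added one at a time; an
   optimal deletion set `X` is maintained and compressed through the
   `2^{|X|}` valid partitions of its endpoints with a unit-capacity
   min-cut per partition (`O(2^k · m²)` total).
4. **Reconstruction** — the 2-coloring is mapped back through guards,
   supernodes, subdivisions and the reduction trace to a full labeling,
   then to concrete ordered haplotypes `(h1, h2)` per member with each
   recombination event localized to a parent→child transmission.

## Worked example

`examples/phase_pedigree.py` phases an eight-member pedigree whose three
doubly heterozygous founders are pairwise co-parents of one-site
heterozygous children — a negative triangle of constraints, so some pair
must agree and one recombination is unavoidable:

```
minimum recombination events k* = 1
     ab: h1=01 h2=00
     ad: h1=01 h2=10
   anna: h1=01 h2=10
     bc: h1=00 h2=01
   bert: h1=00 h2=11
     ca: h1=00 h2=01
   cara: h1=01 h2=10
   dave: h1=01 h2=01
  recombination in cara's transmission to ca
independent event count from the witness: 1
```

`k* = 1` is the proven minimum; `h1` is the paternal haplotype where
parents are known; the final line re-counts events directly from the
haplotypes as a cross-check. `examples/simulate_and_recover.py` and
`examples/reduction_experiment.py` demonstrate simulation-based recovery
and the kernelization benchmark the same way.

The same functionality is scriptable from a shell:

```sh
pedphase2 simulate -n 500 --seed 1 --rate 0.01 --out fam.ped
pedphase2 solve fam.ped --mode minimize --out phased.tsv
pedphase2 solve fam.ped --mode decide -k 2     # exit 0 = YES, 1 = NO
pedphase2 reduce fam.ped -k 0                  # kernelization statistics
```

Input is LINKAGE/PED-style text: `family individual father mother sex`
followed by two alleles (coded 1/2) for each of the two sites. Missing
data (allele 0) and more than two sites are rejected — the model assumes
complete, error-free two-site genotypes.

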