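# Methods

## Model

A pedigree is a set of members with known father/mother links; loops
(multiple inheritance paths, e.g. a member mating with its own
descendant) are allowed, and any member may appear as a parent in many
families. Every member carries a genotype over exactly two biallelic
SNP sites, coded per site as 0 (homozygous 0/0), 1 (homozygous 1/1) or
2 (heterozygous). The model assumes complete and error-free genotypes;
missing data and more than two sites are rejected at parse time.

A haplotype configuration assigns each member an ordered pair of
two-site haplotypes consistent with its genotype; each child haplotype
must be one of the transmitting parent's haplotypes (0 events) or their
between-sites recombinant (1 event). With two sites at most one
crossover per transmission is detectable. The optimization problem is
to minimize the total number of events; the decision problem asks
whether `k` events suffice. Both are solved exactly.

### Signed graph formulation

Members heterozygous at both sites ("grey") are the only ones with a
free phase: `{00,11}` ("green pattern") or `{01,10}` ("red pattern").
Doubly homozygous members are fixed red/green; members heterozygous at
exactly one site are unlabeled — their unordered haplotype pair is
unique, and a crossover between their two haplotypes reproduces one of
them, so recombination *in* such a member is undetectable in principle.

The signed pedigree graph has a vertex per labeled member, a positive
edge per labeled parent–child pair and a negative edge joining the
labeled parents of each unlabeled child. An edge is *frustrated* under
a red/green labeling if positive across the partition or negative
within a side; the minimum number of frustrated edges over labelings of
the grey vertices (the line index) equals the minimum recombination
count. Three refinements are needed for that equality to be exact, and
all three are validated against exhaustive search in the test suite
(`test_acceptance.py::test_graph_model_equals_exhaustive_oracle`):

1. **Forced propagation is single-step.** A doubly homozygous parent
   carries two identical haplotypes, so its gamete is crossover-
   invariant and a grey child's phase is forced to the parent's color
   at no cost. A vertex colored *by* propagation, however, holds two
   distinct haplotypes and can transmit a recombinant, so the forcing
   must not chain: its own grey children keep a genuine cost-1 choice.
   (A red founder above a chain of greys forces only the first link;
   forcing the second can overcount by ignoring a cheaper recombinant
   explanation.)
2. **Pinned transmissions.** For a trio with an unlabeled child (het at
   site t), one grey parent u and one unlabeled co-parent w that is
   heterozygous at the *other* site, w's transmissible set contains
   exactly one haplotype fitting the child, so u must transmit the
   complementary haplotype cj outright — costing one event unless u's
   color equals cj's pattern. This is recorded as a resolved vertex for
   the unlabeled child (preserving "at most one vertex per member")
   joined to u by a positive edge. If u is doubly homozygous, the
   per-site Mendelian checks force a match and no edge is needed.
3. **Hard phase forcing.** A grey child of two unlabeled parents can
   have one phase that is infeasible at *any* cost: each unlabeled
   parent transmits exactly one equal-allele and one opposite-allele
   haplotype whatever crossovers occur, so the green phase requires the
   parents' equal-allele haplotypes to differ (likewise red). When only
   one phase survives, the child's vertex is resolved at construction.

Without refinements 2 and 3 the plain construction undercounts on
random pedigrees (first observed as a 0-versus-1 disagreement with the
exhaustive reference); with them, pipeline, graph model and exhaustive
enumeration agree on every instance the suite generates.

## Data reduction

`reduce_to_fixpoint` shrinks `(G, k)` to `(G', k')` with
`l(G) = l(G') + (k − k')` exactly, recording a trace that is replayed
backwards to extend any optimal labeling of `G'` to `G`. The rules:
delete degree-0 vertices and degree-1 grey vertices (color chosen for
free at replay); delete edges between two resolved vertices, paying one
unit iff frustrated; recolor a grey vertex when one color conflicts
with a strict majority of its incident edges (safe for minimization:
flipping such a vertex in any solution never increases frustration);
in decision mode additionally force a color when the alternative alone
exceeds the remaining budget, declaring a No-instance if both do; and
eliminate every degree-2 grey vertex by case analysis on its two edge
signs and neighbor states (deletion, sometimes paying one unit; merging
into a neighbor; or replacing two negative edges by one positive edge).
The two-neighbor case analysis is extended to parallel edges to a
single neighbor (same flip arguments), so the guarantee that **no grey
vertex of degree below three survives** holds unconditionally. Rules
are driven by a deterministic FIFO worklist; edges between resolved
vertices are cleaned eagerly so the budget rules see a consistent
forced-conflict count of zero.

Budget-free rules preserve the optimum exactly; the budget-dependent
forcing preserves only the decision answer, so `minimize` runs without
it.

## Bipartization and iterative compression

Each positive edge is replaced by two consecutive negative edges
through a fresh grey vertex (line index invariant: the new vertex can
always be placed to save the extra edge). All red vertices are merged
into one supernode and all green into another — parallel edges kept —
and `k+1` parallel negative guard edges pin the supernodes to opposite
sides of any within-budget solution; a pure minimization run uses
`|E|+1` guards, which no optimum can afford to cut. Negating all
weights yields an unsigned multigraph in which frustrated edges are
monochromatic ones: Bipartization by Edge Removal.

The bipartization is solved by iterative compression: edges are
processed in a fixed order (sorted by endpoint ids — the optimum is
order-independent, the order pins down tie-breaking); an optimal
deletion set `X` for the current prefix is kept, and when it stops
working, `X' = X ∪ {e}` is compressed. `X'` is first minimalized (if
dropping a single edge still bipartizes, that smaller set is already
the answer — the compression theorem needs a minimal set); each `X'`
edge is then subdivided into three consecutive edges, middle edges
taking over the role of `X'` (this preserves all cycle parities and
makes any smaller solution disjoint from `X'`), the `2^{|X'|−1}` valid
sidings of the subdivision endpoints are enumerated (first edge's
orientation fixed by color-swap symmetry) and a minimum source/sink
edge cut is computed for each with unit-capacity BFS augmenting paths,
aborting once the target size is exceeded. Self-loops, which can arise
when supernodes absorb a frustrated resolved pair in stand-alone use,
are unconditionally part of every solution. The final 2-coloring is
rooted deterministically (smallest id per component), mapped to
red/green through the supernode sides, and pushed back through the
reduction trace.

`minimize` is a single optimization run of this machinery: the
compression loop itself maintains the exact optimum prefix by prefix,
which subsumes an outer loop that would retry the decision problem with
growing budgets; the reduction's committed cost plus the reduced line
index is `k*`, asserted internally and verified against the
haplotype-level event count in the tests.

## Haplotype reconstruction

Grey members take `{00,11}` or `{01,10}` per their color, all other
members their unique pair. Within each trio the child's pair is
oriented so that `h1` is paternal, choosing the assignment with fewer
events; ties prefer attributing the event to the father (negative-edge
events are inherently ambiguous between the two parents, so a fixed
convention keeps output reproducible), then lexicographic order.
Founders are ordered lexicographically. `count_recombinations` re-counts
events from the haplotypes alone and is used as an independent check
that every witness matches `k*`.

## Simulator

`simgen` emulates large, highly connected, cyclic pedigrees: each
mating takes an existing member as one parent and, with probability
`loop_rate` (default 0.3), another existing member — possibly a
descendant — as the other, closing a cycle; otherwise an external
founder joins. Family sizes are `1 + Poisson(mean_children − 1)`
(default mean 2). Founders draw two haplotypes uniformly from
`{00,01,10,11}` (default), which makes roughly half of all members
labeled and reproduces the benchmark's initial graph sizes (≈n/2
vertices, ≈0.4n positive and ≈0.09n negative edges). Genotypes come
from gene dropping; recombinations are planted either per transmission
(`recomb_rate`, default 0) or as an exact count at uniformly chosen
transmissions. The planted list upper-bounds `k*`: events in members
with fewer than two heterozygous sites, or whose recombinant equals a
parental haplotype, are undetectable in principle, so recovery below
the planted count is expected and correct.

What the simulator does not emulate: genotyping errors and missing
calls, sex-specific inheritance, realistic human demography, linkage-
map-based recombination rates, and more than two sites. Passing tests
therefore certify the combinatorial optimization under the stated
assumptions, not robustness to noisy real-world data.

## The reduction-efficiency experiment

The benchmark (`scripts/acceptance.py`,
`tests/test_acceptance.py::test_reduction_efficiency_experiment`) runs
20 pedigrees with member counts 1000, 1500, …, 10000 plus one replicate
of the largest size, recombination-free gene drop, and reduces the
decision instance at the data's true parameter, `k = 0`. The parameter
choice is part of the experimental design: the reduction rules are
defined on the parameterized instance, and the budget-dependent forcing
is what collapses the residual grey clusters; the budget-free subset
alone leaves degree-≥3 grey blobs and resolved pendants (≈98.5% /
≈97.9% eliminated instead of ≈99.9% / ≈99.9%). Both modes are exposed
(`reduce -k 0` versus `reduce`) and both are tested for soundness.

## Numerical and design choices

* Determinism everywhere: vertex iteration sorted by string key, edges
  by id, FIFO worklists, fixed tie-breaks; identical inputs and seeds
  give byte-identical outputs.
* Arbitrary replay colors (isolated grey vertices, "without loss of
  generality" cases) resolve to green, or to the first-listed neighbor's
  color, as fixed deterministic conventions.
* Exhaustive references guard their input sizes (≤24 grey vertices /
  vertices, ≤12 members) and raise rather than truncate.
* Degenerate inputs: empty graphs and vertex-free pedigrees phase with
  `k* = 0`; self-loops are handled in stand-alone graph utilities even
  though pedigree-built graphs never contain them.
* Budgeted runs abort early (`No`) as soon as the consumed budget
  exceeds `k`, including inside the compression loop.

## Limitations

* Exactly two sites; the multi-site generalization requires additional
  inter-pair consistency machinery and is out of scope.
* No missing data or genotyping-error handling.
* Worst-case exponential in `k` (inherent: the problem is NP-hard);
  practical only because kernelization leaves tiny residual instances
  at realistic recombination densities.
* The witness configuration is one optimum among possibly many; ties
  are broken deterministically, not enumerated.
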