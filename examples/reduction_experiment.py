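"""Kernelization benchmark: how much of the signed graph the rules remove.

Simulates complex looped pedigrees, builds the signed pedigree graph and
applies the data-reduction rules for the decision instance at the
data's parameter (k = 0: the gene drop plants no recombinations).  The
rules routinely eliminate >99% of vertices and edges, which is what
makes the exponential compression step affordable afterwards.
"""

from pedphase2 import SimParams, build_graph, reduce_to_fixpoint, simulate

print(f"{'members':>8} {'vertices':>9} {'pos':>6} {'neg':>6} "
      f"{'red_v':>6} {'red_e':>6} {'v%':>7} {'e%':>7}")
for i, n in enumerate((1000, 2000, 3000, 4000, 5000)):
    pedigree, _ = simulate(SimParams(n_members=n, seed=1000 + i))
    g = build_graph(pedigree)
    red = reduce_to_fixpoint(g, k=0)
    v0, e0 = g.num_vertices, g.num_edges
    v1, e1 = red.graph.num_vertices, red.graph.num_edges
    print(f"{n:>8} {v0:>9} {g.count_edges(+1):>6} {g.count_edges(-1):>6} "
          f"{v1:>6} {e1:>6} {100 * (1 - v1 / v0):>6.2f}% "
          f"{100 * (1 - e1 / e0):>6.2f}%")
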