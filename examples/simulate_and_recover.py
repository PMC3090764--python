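"""Gene-drop a complex looped pedigree, plant recombinations, recover them.

The simulator records the ground truth; the solver's k* can only count
*detectable* events (a crossover between two identical haplotypes
changes nothing), so k* is bounded by the planted count and matches the
exhaustive minimum on small instances.
"""

from pedphase2 import SimParams, minimize, mrhc_bruteforce, simulate

for planted in (0, 2, 4):
    pedigree, truth = simulate(SimParams(
        n_members=120, planted_events=planted, loop_rate=0.3, seed=8))
    result = minimize(pedigree)
    print(f"planted {len(truth.events)} events in 120 members "
          f"-> recovered k* = {result.k_star}")
    assert result.k_star <= len(truth.events)

# on a pedigree small enough for exhaustive search the two agree exactly
pedigree, truth = simulate(SimParams(n_members=10, planted_events=2, seed=3))
print(f"10-member check: k* = {minimize(pedigree).k_star}, "
      f"exhaustive = {mrhc_bruteforce(pedigree)}")
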