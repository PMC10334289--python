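"""Exact multi-set intersection statistics for gene sets.

Five condition gene sets share a planted 45-gene core inside a 2,000-gene
universe; the exact convolution test quantifies how improbable that
shared core would be for independent random sets of the same sizes.
"""

import numpy as np

from dipsig import GeneSet, Universe, derive_signature, fisher_overlap, venn_counts

rng = np.random.default_rng(0)
universe_ids = [f"g{i}" for i in range(2000)]
universe = Universe(frozenset(universe_ids))

core = set(universe_ids[:45])
sets = []
for i in range(5):
    noise = rng.choice(universe_ids[45:], 150, replace=False)
    sets.append(GeneSet(f"condition_{i + 1}", frozenset(core | set(noise))))

signature, result = derive_signature(sets, universe)
print(f"set sizes: {result.set_sizes}, universe: {result.universe_size}")
print(f"intersection: {result.observed} genes (expected {result.expected:.2e} by chance)")
print(f"exact multi-set p = {result.p_value:.3g}  (log10 p = {result.log10_p:.1f})")

pair = fisher_overlap(sets[0], sets[1], universe)
print(f"pairwise Fisher p (set 1 vs 2): {pair.p_value:.3g}")

patterns = venn_counts(sets[:3])
print(f"3-set Venn: {sum(patterns.values())} genes in union, "
      f"{patterns.get((1, 1, 1), 0)} in all three.")
print("\nThe observed 45-gene core vastly exceeds its chance expectation; the")
print("log10 p stays finite even when the p-value underflows double precision.")
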