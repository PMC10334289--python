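"""Gene-length-bias-corrected category enrichment.

Region-derived gene sets over-select long genes.  This example plants a
length-proportional selection, fits the probability weight function, and
shows how the Wallenius test deflates a category confounded with length
while a genuinely enriched category stays on top.
"""

import numpy as np
from scipy import stats

from dipsig import CategoryMap, GeneSet, Universe, enrich_all, fit_pwf

rng = np.random.default_rng(0)
n = 5000
ids = [f"g{i}" for i in range(n)]
lengths = rng.integers(500, 50_000, n).astype(float)
universe = Universe(frozenset(ids))

# selection probability proportional to gene length (the DIP-Seq artifact)
selected = rng.random(n) < 0.4 * lengths / lengths.max()
gene_set = GeneSet("selected", frozenset(np.array(ids)[selected]))
pwf = fit_pwf(selected, lengths, ids)
rho = stats.spearmanr(pwf.weights, lengths).statistic
print(f"{selected.sum()} genes selected; PWF rank-correlation with length: {rho:.3f}")

longest = frozenset(np.array(ids)[np.argsort(lengths)[-200:]])        # confounded
planted = frozenset(rng.choice(np.array(ids)[selected], 150, replace=False))  # real signal
cmap = CategoryMap({
    "long_genes": ("longest 200 genes", longest),
    "planted": ("planted signal", planted),
})
table = enrich_all(gene_set, cmap, universe, pwf)
print(table[["category_id", "n_selected_in_category", "n_category", "odds", "pval", "qval"]]
      .to_string(index=False))
print("\nThe length-confounded category gets odds > 1 and a deflated p-value;")
print("the genuinely enriched category ranks first despite the correction.")
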