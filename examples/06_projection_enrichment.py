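"""Find clusters enriched for a projection target.

For each (cluster, target) pair, the proportion of the target's neurons in
the cluster is tested against all other targets with a one-sided Fisher exact
test (BH-corrected); clusters holding >5% of a projection's cells are
"associated" with it.
"""

import numpy as np

from epiretro.enrichment import enrichment_table

# target A concentrates in cluster X (20 of its 100 cells) while the other
# 900 neurons spread thinly there (10 cells)
clusters = np.array(["X"] * 20 + ["Y"] * 80 + ["X"] * 10 + ["Y"] * 890)
targets = np.array(["A"] * 100 + ["B"] * 900)

tab = enrichment_table(clusters, targets)
print(tab[["cluster", "target", "proportion", "odds_ratio", "fdr", "enriched"]]
      .round(4).to_string(index=False))
row = tab.set_index(["cluster", "target"]).loc[("X", "A")]
print(f"-> cluster X holds {row['proportion']:.0%} of target-A neurons "
      f"(odds ratio {row['odds_ratio']:.2f}, FDR {row['fdr']:.2e}): "
      "a projection-enriched cluster.")
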