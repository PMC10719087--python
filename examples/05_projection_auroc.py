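"""Quantify how separable two projection targets are from gene-body mCH.

An L2 logistic regression predicts the projection target from posterior
gene-body mCH; the held-out AUROC over 50 random half/half splits measures
the epigenomic difference between the two neuron groups.
"""

import numpy as np

from epiretro import SimulationConfig, simulate_multiomic_cohort, posterior_methylation
from epiretro.discriminability import pairwise_projection_auroc

cfg = SimulationConfig(
    n_clusters=2, cells_per_cluster_mc=200, n_genes=300,
    marker_effect=0.3, coverage_mean=50.0, n_projections=2, seed=1,
)
mcm, _, _, truth = simulate_multiomic_cohort(cfg)
levels = posterior_methylation(mcm)
proj = np.array([truth.cell_projection_observed[c] for c in levels.cells])

res = pairwise_projection_auroc(levels.levels, proj, ("target0", "target1"),
                                n_seeds=50, seed=1)
print(f"mean AUROC over {len(res.auroc_values)} splits: {res.mean_auroc:.3f}")

null = pairwise_projection_auroc(
    levels.levels, np.random.default_rng(1).permutation(proj),
    ("target0", "target1"), n_seeds=50, seed=1,
)
print(f"label-permuted null AUROC: {null.mean_auroc:.3f}")
print("-> ~1.0 vs ~0.5: the planted methylation difference between targets is "
      "fully detectable, and vanishes when labels carry no information.")
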