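"""Run the contamination gate on a handful of FANS runs.

Each run's observed on-/off-target neuron counts are compared to the expected
split from unbiased reference data: fold enrichment FE = (O_on E_off)/(O_off
E_on) and a one-sided exact binomial p value, BH-corrected.  Extratelencephalic
(ET) targets use the stricter FE >= 8 gate.
"""

import pandas as pd

from epiretro.qc import contamination_test_batch

runs = pd.DataFrame(
    {
        "run_id": ["clean_run", "weak_run", "contaminated_run"],
        "o_on": [95, 40, 12],
        "o_off": [5, 60, 88],
        "e_on": [10, 10, 10],     # unbiased data: 10% of neurons are on-target
        "e_off": [90, 90, 90],
    }
)
out = contamination_test_batch(runs, fe_threshold=8.0, fdr_threshold=0.001)
print(out[["run_id", "fold_enrichment", "p_value", "fdr", "passed"]].to_string(index=False))
print("-> only runs whose on-target enrichment is both large (FE >= 8) and "
      "statistically solid (FDR < 0.001) keep their projection label.")
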