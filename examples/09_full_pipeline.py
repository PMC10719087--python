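"""Run the end-to-end pipeline on a synthetic cohort and read the manifest.

Stages run in dependency order (simulate -> QC -> clustering -> enrichment ->
AUROC -> regulatory -> spatial); the manifest records the config hash, all
seeds, and per-stage summaries, so every number is reproducible from it.
"""

import json

from epiretro.simulate import SimulationConfig
from epiretro.workflows import PipelineConfig, run_pipeline

config = PipelineConfig(
    out_dir="scratch/pipeline_demo",
    seed=1,
    simulation=SimulationConfig(
        seed=1, n_clusters=3, cells_per_cluster_mc=40, cells_per_cluster_rna=20,
        n_genes=80, n_projections=2,
    ),
    auroc_n_seeds=5,
    n_components=6,
    knn_k=10,
    grn_params=dict(n_clusters=20, n_tfs=4, n_genes=20, n_dmrs=30, n_triplets=3),
)
manifest = run_pipeline(config)
print(f"config hash: {manifest['config_hash']}")
for stage, info in manifest["stages"].items():
    summary = {k: v for k, v in info.items() if k not in ("outputs", "wall_time_s")}
    print(f"  {stage}: {json.dumps(summary, default=str)}")
print("-> outputs and manifest.json are under scratch/pipeline_demo/.")
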