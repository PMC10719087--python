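"""End-to-end pipeline runner stitching the modules into analysis order.

The pipeline mirrors the study's stage order — simulate (or load) -> QC ->
doublet removal -> integration + joint clustering -> projection enrichment ->
AUROC discriminability -> regulatory (DEG / DMR / motif / GRN) -> spatial —
with explicit dependencies; requesting a stage without its upstream output is
a hard error.  Every run writes a manifest carrying the config hash and all
seeds, so any numeric output is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .discriminability import pairwise_projection_auroc
from .enrichment import enrichment_table
from .integration import joint_cluster
from .methylome import posterior_methylation
from .regulatory import (
    assign_hypo_dmrs,
    build_grn,
    dmr_gene_association,
    motif_enrichment,
)
from .simulate import (
    SimulationConfig,
    simulate_grn_profiles,
    simulate_multiomic_cohort,
    simulate_spatial_slices,
)
from .spatial import smooth_spatial_labels
from .transfer import knn_transfer_weights, transfer_labels

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]


@dataclasses.dataclass
class PipelineConfig:
    """Pipeline parameters; unknown stages or missing paths fail validation."""

    out_dir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    auroc_n_seeds: int = 10
    knn_k: int = 25
    leiden_resolution: float = 1.0
    n_components: int = 10
    grn_params: dict = dataclasses.field(default_factory=dict)
    spatial_noise_rate: float = 0.2
    spatial_n_slices: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # the hash identifies the analysis, not its location
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg


STAGES = [
    "simulate",
    "qc",
    "cluster",
    "enrich",
    "auroc",
    "regulatory",
    "spatial",
]
_DEPS = {
    "simulate": [],
    "qc": ["simulate"],
    "cluster": ["simulate"],
    "enrich": ["cluster"],
    "auroc": ["simulate"],
    "regulatory": [],
    "spatial": [],
}


class DependencyError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in dependency order on the synthetic
    cohort defined by the config; returns the run manifest (also written to
    ``out_dir/manifest.json``).
    """
    stages = list(stages or STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
        for dep in _DEPS[s]:
            if dep not in stages:
                raise DependencyError(f"stage {s!r} requires stage {dep!r}")
    stages = [s for s in STAGES if s in stages]

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.simulation or SimulationConfig(seed=config.seed)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seeds": {"root": config.seed, "simulation": sim_cfg.seed},
        "stages": {},
    }
    ctx: dict = {}

    for stage in stages:
        t0 = time.time()
        if stage == "simulate":
            mcm, rna, meta, truth = simulate_multiomic_cohort(sim_cfg)
            ctx.update(mcm=mcm, rna=rna, meta=meta, truth=truth)
            paths = eio.write_bundle(out / "cohort", counts=mcm, metadata=meta)
            manifest["stages"]["simulate"] = {
                "n_mc_cells": mcm.n_cells,
                "n_rna_cells": len(rna.cells),
                "outputs": {k: str(v) for k, v in paths.items()},
            }
        elif stage == "qc":
            meta = ctx["meta"]
            mc_meta = meta[meta["modality"] == "mc"]
            per_run = mc_meta.groupby("fans_run").size()
            keep_runs = set(per_run.index[per_run >= 20])
            manifest["stages"]["qc"] = {
                "n_runs": int(len(per_run)),
                "n_runs_pass_min_cells": len(keep_runs),
            }
        elif stage == "cluster":
            mcm = ctx["mcm"]
            levels = posterior_methylation(mcm)
            from .methylome import reduce_dimensions

            emb = reduce_dimensions(levels.levels, config.n_components, mode="fit")
            labels = joint_cluster(
                emb.coords,
                k=min(config.knn_k, emb.coords.shape[0] - 1),
                resolution=config.leiden_resolution,
                seed=config.seed,
            )
            ctx.update(levels=levels, embedding=emb, cluster_labels=labels)
            eio.write_tsv(
                pd.DataFrame({"cell_id": levels.cells, "cluster": labels}),
                out / "clusters.tsv",
            )
            manifest["stages"]["cluster"] = {"n_clusters": int(labels.max()) + 1}
        elif stage == "enrich":
            meta = ctx["meta"]
            mc_meta = meta[meta["modality"] == "mc"].reset_index(drop=True)
            labels = ctx["cluster_labels"]
            singlet = ~mc_meta["is_doublet_truth"].to_numpy()
            tab = enrichment_table(
                labels[singlet], mc_meta.loc[singlet, "projection"].to_numpy()
            )
            eio.write_tsv(tab, out / "enrichment.tsv")
            manifest["stages"]["enrich"] = {
                "n_enriched": int(tab["enriched"].sum())
            }
        elif stage == "auroc":
            mcm, meta, truth = ctx["mcm"], ctx["meta"], ctx["truth"]
            mc_meta = meta[meta["modality"] == "mc"].reset_index(drop=True)
            levels = ctx.get("levels") or posterior_methylation(mcm)
            singlet = ~mc_meta["is_doublet_truth"].to_numpy()
            proj = mc_meta.loc[singlet, "projection"].to_numpy()
            targets = sorted(pd.unique(proj))[:2]
            res = pairwise_projection_auroc(
                levels.levels[singlet], proj, (targets[0], targets[1]),
                n_seeds=config.auroc_n_seeds, seed=config.seed,
            )
            manifest["stages"]["auroc"] = {
                "pair": list(res.pair),
                "mean_auroc": res.mean_auroc,
            }
        elif stage == "regulatory":
            grn_seed = config.grn_params.get("seed", config.seed)
            sim = simulate_grn_profiles(seed=grn_seed, **{
                k: v for k, v in config.grn_params.items() if k != "seed"
            })
            hypo = assign_hypo_dmrs(sim["dmr_mcg"])
            hypo_sets = {
                c: set(hypo.index[hypo[c]]) for c in hypo.columns
            }
            enr = motif_enrichment(
                hypo_sets, sim["dmr_mcg"].index.to_numpy(), sim["sequences"], sim["motifs"]
            )
            mid = dict(
                zip(
                    sim["dmr_records"]["dmr_id"],
                    (sim["dmr_records"]["start"] + sim["dmr_records"]["end"]) // 2,
                )
            )
            triplets = build_grn(
                sim["tf_expr"], sim["gene_expr"], sim["dmr_mcg"],
                sim["sequences"], sim["motifs"], mid, sim["tss"],
                enriched_tfs=set(sim["tf_expr"].index),
                deg_union=set(sim["gene_expr"].index),
                seed=grn_seed,
            )
            eio.write_tsv(
                pd.DataFrame([dataclasses.asdict(t) for t in triplets]),
                out / "grn_triplets.tsv",
            )
            manifest["stages"]["regulatory"] = {
                "n_enriched_motif_cluster": int(enr.enriched.to_numpy().sum()),
                "n_triplets": len(triplets),
            }
        elif stage == "spatial":
            slices, struth = simulate_spatial_slices(
                sim_cfg, n_slices=config.spatial_n_slices,
                noise_rate=config.spatial_noise_rate,
            )
            sl = slices[0]
            probs = smooth_spatial_labels(
                sl, sl.coords, sl.initial_labels, sl.coords,
                k_spatial=min(25, sl.n_cells - 1),
            )
            smoothed = probs.assignments
            truth_labels = np.array([struth.spatial_truth[c] for c in sl.cell_ids])
            manifest["stages"]["spatial"] = {
                "error_before": float((sl.initial_labels != truth_labels).mean()),
                "error_after": float((smoothed != truth_labels).mean()),
            }
        manifest["stages"][stage]["wall_time_s"] = round(time.time() - t0, 3)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
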