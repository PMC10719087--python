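"""Planted-truth recovery benchmarks on synthetic cohorts.

Each function generates a seeded synthetic dataset with
:mod:`epiretro.simulate`, runs one stage of the analysis on it, and scores the
result against the planted ground truth.  They define the package's standard
evaluation conditions — sample sizes, effect sizes, noise levels — and return
plain dicts of the measured quantities, so the same computation backs both the
test suite and the reproducibility script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .discriminability import gene_category_auroc, pairwise_projection_auroc
from .enrichment import enrichment_table
from .methylome import normalize_rna, posterior_methylation
from .motifs import MotifPwm
from .qc import contamination_test_batch
from .regulatory import (
    build_grn,
    dmr_gene_association,
    motif_enrichment,
    pairwise_degs,
)
from .simulate import (
    SimulationConfig,
    simulate_grn_profiles,
    simulate_motif_regions,
    simulate_multiomic_cohort,
    simulate_spatial_slices,
)
from .spatial import smooth_spatial_labels
from .transfer import knn_transfer_weights, remove_doublets, transfer_labels
from .methylome import reduce_dimensions

__all__ = [
    "auroc_benchmark",
    "gene_category_benchmark",
    "label_transfer_benchmark",
    "enrichment_benchmark",
    "contamination_benchmark",
    "deg_benchmark",
    "dmr_gene_benchmark",
    "motif_benchmark",
    "grn_benchmark",
    "spatial_benchmark",
]


def _mid(records: pd.DataFrame) -> dict:
    return dict(zip(records["dmr_id"], (records["start"] + records["end"]) // 2))


def auroc_benchmark(seed: int = 1, n_seeds: int = 50) -> dict:
    """Projection-pair separability on a planted-signal cohort.

    Two clusters mapping to two targets, 200 cells per class, marker genes
    hypomethylated to 0.3x in their cluster, ~50 basecalls per gene.  Reports
    the mean AUROC over resampled half/half splits, and the same quantity
    after permuting the projection labels (the null).
    """
    cfg = SimulationConfig(
        n_clusters=2,
        cells_per_cluster_mc=200,
        n_genes=300,
        marker_effect=0.3,
        coverage_mean=50.0,
        n_projections=2,
        seed=seed,
    )
    mcm, _, _, truth = simulate_multiomic_cohort(cfg)
    levels = posterior_methylation(mcm)
    proj = np.array([truth.cell_projection_observed[c] for c in levels.cells])
    res = pairwise_projection_auroc(
        levels.levels, proj, ("target0", "target1"), n_seeds=n_seeds, seed=seed
    )
    perm = np.random.default_rng(seed).permutation(proj)
    null = pairwise_projection_auroc(
        levels.levels, perm, ("target0", "target1"), n_seeds=n_seeds, seed=seed
    )
    n = int(sum(res.n_per_class))
    return {
        "mean_auroc": float(res.mean_auroc),
        "null_auroc": float(null.mean_auroc),
        "n_cells": n,
        "n_seeds": n_seeds,
    }


def gene_category_benchmark(seed: int = 1, n_seeds: int = 5) -> dict:
    """Signal-bearing gene category versus size-matched random genes.

    Nine clusters map one-to-one onto nine targets (36 target-pair
    comparisons); the "signal" category holds every planted marker gene, the
    "random" category an equal number of non-markers.  Paired two-sided
    Wilcoxon signed-rank across comparisons, BH-adjusted.
    """
    cfg = SimulationConfig(
        n_clusters=9,
        cells_per_cluster_mc=40,
        n_genes=300,
        marker_fraction=0.3,
        marker_effect=0.3,
        coverage_mean=50.0,
        n_projections=9,
        seed=seed,
    )
    mcm, _, _, truth = simulate_multiomic_cohort(cfg)
    levels = posterior_methylation(mcm)
    frame = levels.frame()
    proj = np.array([truth.cell_projection_observed[c] for c in levels.cells])
    markers = sorted(set().union(*truth.markers_per_cluster.values()))
    nonmarkers = [g for g in frame.columns if g not in set(markers)]
    rng = np.random.default_rng(seed)
    categories = {
        "signal": markers,
        "random": list(rng.choice(nonmarkers, size=len(markers), replace=False)),
    }
    targets = sorted(pd.unique(proj))
    comparisons = [
        (targets[i], targets[j])
        for i in range(len(targets))
        for j in range(i + 1, len(targets))
    ]
    long, tests = gene_category_auroc(
        frame, proj, categories, comparisons, n_seeds=n_seeds, seed=seed
    )
    wide = long.pivot(index="comparison", columns="category", values="auroc")
    row = tests.iloc[0]
    return {
        "n_comparisons": len(comparisons),
        "signal_median_auroc": float(wide["signal"].median()),
        "random_median_auroc": float(wide["random"].median()),
        "fdr": float(row["fdr"]),
        "signal_beats_random": bool(
            wide["signal"].median() > wide["random"].median() and row["fdr"] < 0.01
        ),
    }


def label_transfer_benchmark(seed: int = 1) -> dict:
    """Cluster assignment accuracy and doublet flagging on a split cohort.

    One cohort (four separable clusters, a quarter synthetic 50/50 doublets)
    is split 65/35 into a labelled reference and a query; the reference must
    carry enough doublet exemplars per cluster pair for the kNN vote.
    """
    cfg = SimulationConfig(
        n_clusters=4,
        cells_per_cluster_mc=100,
        n_genes=200,
        marker_fraction=0.4,
        marker_effect=0.15,
        coverage_mean=150.0,
        doublet_fraction=0.25,
        seed=seed,
    )
    mcm, _, _, truth = simulate_multiomic_cohort(cfg)
    levels = posterior_methylation(mcm)
    clusters = np.array([truth.cell_cluster[c] for c in levels.cells], dtype=object)
    is_dbl = np.array([c in truth.doublet_ids for c in levels.cells])
    rng = np.random.default_rng(seed)
    ref = rng.random(len(levels.cells)) < 0.65
    qry = ~ref

    assigned, flags = remove_doublets(
        levels.levels[qry], levels.levels[ref], clusters[ref], is_dbl[ref],
        k=5, n_components=10,
    )
    truth_q = is_dbl[qry]
    singlet_q = ~truth_q & ~flags
    acc = (assigned[singlet_q] == clusters[qry][singlet_q]).mean()
    return {
        "cluster_accuracy": float(acc),
        "doublet_sensitivity": float(flags[truth_q].mean()),
        "singlet_false_flag": float(flags[~truth_q].mean()),
        "n_query": int(qry.sum()),
    }


def enrichment_benchmark(seed: int = 1, n_null: int = 20) -> dict:
    """Planted projection-enriched cluster plus null false-positive count.

    The planted design holds one cluster with ~20x odds of target-A
    membership; the null replicates assign clusters and targets uniformly.
    """
    rng = np.random.default_rng(seed)
    clusters = np.array(["X"] * 20 + ["Y"] * 80 + ["X"] * 10 + ["Y"] * 890)
    targets = np.array(["A"] * 100 + ["B"] * 900)
    tab = enrichment_table(clusters, targets).set_index(["cluster", "target"])
    planted_hit = bool(tab.loc[("X", "A"), "enriched"])

    false_total = 0
    for _ in range(n_null):
        c = rng.choice([f"c{i}" for i in range(8)], size=1000)
        t = rng.choice(["A", "B", "C"], size=1000)
        false_total += int(enrichment_table(c, t)["enriched"].sum())
    return {
        "planted_odds_ratio": float(tab.loc[("X", "A"), "odds_ratio"]),
        "planted_recovered": planted_hit,
        "null_false_clusters": false_total,
        "n_null_replicates": n_null,
    }


def contamination_benchmark(seed: int = 1, n_runs: int = 10_000) -> dict:
    """Null pass rate and planted-enrichment detection of the FANS gate.

    Null runs draw the observed on-target count from the expected binomial;
    planted runs have a 10x enriched on-target proportion with n >= 50.
    """
    rng = np.random.default_rng(seed)
    n = rng.integers(20, 200, size=n_runs)
    p = rng.uniform(0.05, 0.5, size=n_runs)
    o_on = rng.binomial(n, p)
    null_runs = pd.DataFrame(
        {
            "run_id": [f"null{i}" for i in range(n_runs)],
            "o_on": o_on,
            "o_off": n - o_on,
            "e_on": p * 1000,
            "e_off": (1 - p) * 1000,
        }
    )
    null_out = contamination_test_batch(null_runs, fe_threshold=8.0)

    n2 = rng.integers(50, 200, size=n_runs)
    p_exp = np.full(n_runs, 0.05)
    p_obs = np.minimum(10 * p_exp, 0.95)
    o2 = rng.binomial(n2, p_obs)
    planted_runs = pd.DataFrame(
        {
            "run_id": [f"pl{i}" for i in range(n_runs)],
            "o_on": o2,
            "o_off": n2 - o2,
            "e_on": p_exp * 1000,
            "e_off": (1 - p_exp) * 1000,
        }
    )
    planted_out = contamination_test_batch(planted_runs, fe_threshold=8.0)
    return {
        "null_pass_rate": float(null_out["passed"].mean()),
        "planted_detection_rate": float(planted_out["passed"].mean()),
        "n_runs": n_runs,
    }


def deg_benchmark(seed: int = 1) -> dict:
    """Recovery of planted differentially expressed genes.

    Two clusters whose marker genes carry a 4x expression shift through the
    methylation-expression inverse link (marker_effect = 0.25).
    """
    cfg = SimulationConfig(
        n_clusters=2,
        cells_per_cluster_mc=10,
        cells_per_cluster_rna=80,
        n_genes=300,
        marker_effect=0.25,
        coverage_mean=50.0,
        seed=seed,
    )
    _, rna, meta, truth = simulate_multiomic_cohort(cfg)
    expr = normalize_rna(rna.counts, cells=rna.cells, genes=rna.genes)
    rna_meta = meta[meta["modality"] == "rna"].set_index("cell_id")
    clusters = rna_meta.loc[expr.cells, "cluster"].to_numpy()
    union, _ = pairwise_degs(expr.frame(), clusters)
    planted = truth.planted_dmgs[(0, 1)]
    recall = len(union & planted) / len(planted)
    fdr = len(union - planted) / max(len(union), 1)
    return {
        "recall": float(recall),
        "empirical_fdr": float(fdr),
        "n_planted": len(planted),
        "n_found": len(union),
    }


def dmr_gene_benchmark(
    seed: int = 1,
    n_planted: int = 200,
    n_null_per_gene: int = 10,
    n_clusters: int = 30,
    rho: float = 0.9,
) -> dict:
    """Recovery of planted DMR-gene correlations at the shuffle FDR gate.

    Each planted pair shares a latent cluster profile with correlation
    ``rho``; ``n_null_per_gene`` additional DMRs sit within the window of each
    gene but are uncorrelated (2,000 null candidates at the defaults).
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_planted)]
    tss = {g: 2_000_000 + i * 30_000_000 for i, g in enumerate(genes)}

    gene_vals = rng.normal(size=(n_planted, n_clusters))
    dmr_rows, dmr_ids, mid = [], [], {}
    planted_pairs = set()
    for i, g in enumerate(genes):
        d_id = f"d_pl{i}"
        noise = rng.normal(size=n_clusters)
        dmr_rows.append(rho * gene_vals[i] + np.sqrt(1 - rho**2) * noise)
        dmr_ids.append(d_id)
        mid[d_id] = tss[g] + int(rng.integers(-500_000, 500_000))
        planted_pairs.add((d_id, g))
        for j in range(n_null_per_gene):
            nd = f"d_null{i}_{j}"
            dmr_rows.append(rng.normal(size=n_clusters))
            dmr_ids.append(nd)
            mid[nd] = tss[g] + int(rng.integers(-500_000, 500_000))

    dmr_mcg = pd.DataFrame(dmr_rows, index=dmr_ids)
    gene_mch = pd.DataFrame(gene_vals, index=genes)
    out = dmr_gene_association(
        dmr_mcg, gene_mch, mid, tss, n_shuffles=100, seed=seed
    )
    sig = out.loc[out["significant"]]
    got = set(map(tuple, sig[["dmr", "gene"]].to_numpy()))
    recall = len(got & planted_pairs) / n_planted
    fdr = len(got - planted_pairs) / max(len(got), 1)
    return {
        "recall": float(recall),
        "empirical_fdr": float(fdr),
        "n_candidates": len(out),
        "n_planted": n_planted,
    }


def motif_benchmark(seed: int = 1, n_background: int = 49, n_dmrs: int = 300) -> dict:
    """NES of a planted motif against a background collection.

    A quarter of the DMR sequences carry the planted motif and form the
    hypo-set; background motifs are random sharp PWMs of the same width.
    """
    rng = np.random.default_rng(seed)

    def _random_motif(name):
        mat = np.full((8, 4), 0.02)
        mat[np.arange(8), rng.integers(0, 4, 8)] = 0.94
        return MotifPwm(name, mat)

    target = _random_motif("planted")
    records, seqs = simulate_motif_regions(n_dmrs, target, 0.25, seed=seed)
    fg = set(records.loc[records["planted"], "dmr_id"])
    motifs = [target] + [_random_motif(f"bg{i}") for i in range(n_background)]
    res = motif_enrichment({"c0": fg}, records["dmr_id"].to_numpy(), seqs, motifs)
    bg_nes = res.nes.drop(index="planted")["c0"]
    return {
        "planted_nes": float(res.nes.loc["planted", "c0"]),
        "planted_enriched": bool(res.enriched.loc["planted", "c0"]),
        "background_below_cutoff": float((bg_nes < 3).mean()),
        "n_motifs": len(motifs),
    }


def grn_benchmark(seed: int = 1) -> dict:
    """Precision and recall of planted TF-DMR-target triplets."""
    sim = simulate_grn_profiles(n_clusters=30, n_triplets=10, seed=seed)
    triplets = build_grn(
        sim["tf_expr"], sim["gene_expr"], sim["dmr_mcg"],
        sim["sequences"], sim["motifs"], _mid(sim["dmr_records"]), sim["tss"],
        enriched_tfs=set(sim["tf_expr"].index),
        deg_union=set(sim["gene_expr"].index),
        n_shuffles=100, seed=seed,
    )
    got = {(t.tf, t.dmr, t.target) for t in triplets}
    planted = set(sim["triplets"])
    recall = len(got & planted) / len(planted)
    precision = len(got & planted) / max(len(got), 1)
    return {
        "recall": float(recall),
        "precision": float(precision),
        "n_planted": len(planted),
        "n_found": len(got),
    }


def spatial_benchmark(seed: int = 1, n_replicates: int = 20) -> dict:
    """Error reduction from product-weight smoothing on noisy slices.

    Each replicate is a fresh slice (five regions, 20% flipped labels); the
    smoothed assignment must beat the noisy one in every replicate.
    """
    wins = 0
    before, after = [], []
    for r in range(n_replicates):
        cfg = SimulationConfig(seed=seed + r, n_clusters=5, cells_per_cluster_mc=40)
        slices, truth = simulate_spatial_slices(cfg, n_slices=1, noise_rate=0.2)
        sl = slices[0]
        truth_labels = np.array([truth.spatial_truth[c] for c in sl.cell_ids])
        probs = smooth_spatial_labels(
            sl, sl.coords, sl.initial_labels, sl.coords, k_spatial=15, k_ref=15
        )
        e0 = (sl.initial_labels != truth_labels).mean()
        e1 = (probs.assignments != truth_labels).mean()
        wins += e1 < e0
        before.append(e0)
        after.append(e1)
    return {
        "replicates_improved": int(wins),
        "n_replicates": n_replicates,
        "mean_error_before": float(np.mean(before)),
        "mean_error_after": float(np.mean(after)),
    }
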