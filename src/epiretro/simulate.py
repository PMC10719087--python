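"""Synthetic multi-modal cohorts with recorded ground truth.

The generator emulates the statistical structure of projection-labelled
single-nucleus methylome data and its companion modalities:

* per-cell, per-gene methylated/total basecall counts, with total coverage
  Poisson(coverage_mean) and methylated counts Binomial(coverage, rate);
* cluster structure through marker genes whose non-CG methylation rate is
  multiplied by ``marker_effect`` (< 1: hypomethylated) in their own cluster;
* RNA cells whose expression mean is inversely linked to the methylation rate
  (expression = base * global_mch_mean / rate), negative-binomially sampled —
  gene-body mCH and expression are anticorrelated by construction;
* doublets as 50/50 mixtures of two random clusters' rate profiles;
* projection-target labels assigned per cluster, with a controllable fraction
  reassigned uniformly (contamination);
* spatial slices with contiguous region blocks and clustered label noise;
* DMR sequences with planted motif instances.

One seeded :class:`numpy.random.Generator` drives everything; an identical
config yields byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .methylome import FeatureSet, MethylCountMatrix
from .motifs import MotifPwm, motif_hit_threshold
from .spatial import SpatialSlice

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "RnaCountMatrix",
    "simulate_multiomic_cohort",
    "simulate_spatial_slices",
    "simulate_motif_regions",
    "simulate_grn_profiles",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort generation parameters; all randomness flows from ``seed``."""

    n_clusters: int = 5
    cells_per_cluster_mc: int = 60
    cells_per_cluster_rna: int = 60
    n_genes: int = 300
    n_bins: int = 100
    global_mch_mean: float = 0.04
    global_mcg_mean: float = 0.75
    marker_fraction: float = 0.2
    marker_effect: float = 0.3
    coverage_mean: float = 100.0
    doublet_fraction: float = 0.0
    contamination_fraction: float = 0.0
    n_projections: int = 2
    n_sources: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "global_mch_mean", "global_mcg_mean", "marker_fraction",
            "doublet_fraction", "contamination_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.doublet_fraction >= 1.0:
            raise ValueError("doublet_fraction must be < 1")
        for name in (
            "n_clusters", "cells_per_cluster_mc", "cells_per_cluster_rna",
            "n_genes", "n_bins", "n_projections", "n_sources",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.marker_fraction * self.n_genes < 1:
            raise ValueError("marker_fraction * n_genes must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth recorded alongside every simulated cohort."""

    cell_cluster: dict = field(default_factory=dict)
    cell_projection_true: dict = field(default_factory=dict)
    cell_projection_observed: dict = field(default_factory=dict)
    markers_per_cluster: dict = field(default_factory=dict)
    planted_dmgs: dict = field(default_factory=dict)   # (cluster_a, cluster_b) -> gene set
    planted_dmrs: list = field(default_factory=list)
    planted_motif: dict = field(default_factory=dict)
    doublet_ids: set = field(default_factory=set)
    doublet_pairs: dict = field(default_factory=dict)  # cell -> (cluster_a, cluster_b)
    spatial_truth: dict = field(default_factory=dict)
    rates: np.ndarray | None = None                    # cluster x gene methylation rates
    triplets: list = field(default_factory=list)

    def projection_dmgs(self, target_a, target_b, cluster_to_target: dict) -> set:
        """Genes expected to differ between two projection targets: markers of
        the clusters assigned to either target (and not both)."""
        genes_a = set().union(
            *[self.markers_per_cluster[c] for c, t in cluster_to_target.items() if t == target_a]
        )
        genes_b = set().union(
            *[self.markers_per_cluster[c] for c, t in cluster_to_target.items() if t == target_b]
        )
        return genes_a ^ genes_b


@dataclass
class RnaCountMatrix:
    """Cell-by-gene UMI counts."""

    cells: np.ndarray
    genes: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValueError("count matrix shape mismatch")


def _gene_features(n_genes: int) -> FeatureSet:
    rows = [
        (f"gene{j}", "chr1", j * 10_000, j * 10_000 + 3_000, "gene_body_ext2kb", "+")
        for j in range(n_genes)
    ]
    return FeatureSet(
        pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end", "kind", "strand"])
    )


def simulate_multiomic_cohort(
    config: SimulationConfig,
) -> tuple[MethylCountMatrix, RnaCountMatrix, pd.DataFrame, GroundTruth]:
    """Generate paired methylome and RNA cohorts with planted cluster markers.

    Returns (methylation counts, RNA counts, cell metadata, ground truth).
    Metadata covers both modalities (column ``modality`` in {"mc", "rna"}) and
    carries cluster, observed projection target, sex, source, FANS run and
    replicate columns.
    """
    rng = np.random.default_rng(config.seed)
    K, G = config.n_clusters, config.n_genes
    truth = GroundTruth()

    # per-gene baseline mCH rates around the global mean, cluster-specific markers
    base = np.clip(
        config.global_mch_mean * rng.lognormal(0.0, 0.4, size=G), 1e-4, 0.95
    )
    rates = np.tile(base, (K, 1))
    n_markers = int(round(config.marker_fraction * G))
    marker_genes = rng.choice(G, size=n_markers, replace=False)
    for m_idx, g in enumerate(marker_genes):
        c = m_idx % K
        rates[c, g] = np.clip(base[g] * config.marker_effect, 1e-5, 0.95)
        truth.markers_per_cluster.setdefault(c, set()).add(f"gene{g}")
    for c in range(K):
        truth.markers_per_cluster.setdefault(c, set())
    for a in range(K):
        for b in range(a + 1, K):
            truth.planted_dmgs[(a, b)] = (
                truth.markers_per_cluster[a] ^ truth.markers_per_cluster[b]
            )
    truth.rates = rates

    # ---- methylation cells -------------------------------------------------
    n_mc = K * config.cells_per_cluster_mc
    clusters_mc = np.repeat(np.arange(K), config.cells_per_cluster_mc)
    n_doublets = int(round(config.doublet_fraction * n_mc))
    cell_rates = rates[clusters_mc]
    mc_ids = np.array([f"mc{i}" for i in range(n_mc + n_doublets)])
    is_doublet = np.zeros(n_mc + n_doublets, dtype=bool)

    if n_doublets:
        pairs = np.array(
            [rng.choice(K, size=2, replace=False) for _ in range(n_doublets)]
        )
        doublet_rates = (rates[pairs[:, 0]] + rates[pairs[:, 1]]) / 2.0
        cell_rates = np.vstack([cell_rates, doublet_rates])
        is_doublet[n_mc:] = True
        for i in range(n_doublets):
            cid = mc_ids[n_mc + i]
            truth.doublet_ids.add(cid)
            truth.doublet_pairs[cid] = tuple(sorted(pairs[i]))

    cov = rng.poisson(config.coverage_mean, size=cell_rates.shape)
    mc = rng.binomial(cov, cell_rates)
    genes_fs = _gene_features(G)
    mcm = MethylCountMatrix(cells=mc_ids, features=genes_fs, mc=mc, cov=cov, context="CH")

    cluster_labels_mc = np.array(
        [str(c) for c in clusters_mc] + ["doublet"] * n_doublets, dtype=object
    )
    for cid, lab in zip(mc_ids, cluster_labels_mc):
        truth.cell_cluster[cid] = lab

    # ---- projection targets ------------------------------------------------
    cluster_to_target = {c: f"target{c % config.n_projections}" for c in range(K)}
    proj_true = np.array(
        [
            cluster_to_target[int(lab)] if lab != "doublet" else "doublet"
            for lab in cluster_labels_mc
        ],
        dtype=object,
    )
    proj_obs = proj_true.copy()
    singlet_idx = np.flatnonzero(~is_doublet)
    n_contam = int(round(config.contamination_fraction * singlet_idx.size))
    if n_contam:
        flip = rng.choice(singlet_idx, size=n_contam, replace=False)
        targets = [f"target{t}" for t in range(config.n_projections)]
        proj_obs[flip] = rng.choice(targets, size=n_contam)
    for cid, pt, po in zip(mc_ids, proj_true, proj_obs):
        truth.cell_projection_true[cid] = pt
        truth.cell_projection_observed[cid] = po

    # ---- RNA cells ---------------------------------------------------------
    n_rna = K * config.cells_per_cluster_rna
    clusters_rna = np.repeat(np.arange(K), config.cells_per_cluster_rna)
    base_expr = rng.lognormal(np.log(3.0), 0.5, size=G)
    expr_mean = base_expr[None, :] * (config.global_mch_mean / rates)  # K x G
    lam = rng.gamma(shape=10.0, scale=expr_mean[clusters_rna] / 10.0)
    rna_counts = rng.poisson(lam)
    rna_ids = np.array([f"rna{i}" for i in range(n_rna)])
    rna = RnaCountMatrix(
        cells=rna_ids,
        genes=genes_fs.ids,
        counts=rna_counts,
    )
    for cid, c in zip(rna_ids, clusters_rna):
        truth.cell_cluster[cid] = str(c)

    # ---- metadata ----------------------------------------------------------
    def _meta(ids, clusters, modality, projection=None):
        n = len(ids)
        sex = np.where(np.arange(n) % 2 == 0, "M", "F")
        source = np.array([f"source{i % config.n_sources}" for i in range(n)])
        rows = pd.DataFrame(
            {
                "cell_id": ids,
                "modality": modality,
                "cluster": clusters,
                "sex": sex,
                "source": source,
                "replicate": np.where(np.arange(n) % 4 < 2, "rep1", "rep2"),
            }
        )
        rows["projection"] = projection if projection is not None else pd.NA
        rows["fans_run"] = (
            rows["source"].astype(str)
            + "_"
            + rows["projection"].astype(str)
            + "_"
            + rows["sex"]
        )
        return rows

    meta = pd.concat(
        [
            _meta(mc_ids, cluster_labels_mc, "mc", proj_obs),
            _meta(rna_ids, clusters_rna.astype(str), "rna"),
        ],
        ignore_index=True,
    )
    meta["is_doublet_truth"] = meta["cell_id"].map(
        lambda c: c in truth.doublet_ids
    )
    truth.cluster_to_target = cluster_to_target  # type: ignore[attr-defined]
    return mcm, rna, meta, truth


def simulate_spatial_slices(
    config: SimulationConfig,
    n_slices: int,
    noise_rate: float,
    cells_per_region: int | None = None,
    block_size: float = 100.0,
    block_gap: float = 200.0,
) -> tuple[list[SpatialSlice], GroundTruth]:
    """Slices of spatially contiguous region blocks with flipped-label noise.

    Each of ``config.n_clusters`` regions occupies one square block per slice,
    blocks separated by ``block_gap`` µm so neighbourhoods stay within-region.
    Exactly ``round(noise_rate * n_cells)`` initial labels per slice are
    flipped to a uniformly drawn different region.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if not 0.0 <= noise_rate < 1.0:
        raise ValueError("noise_rate must be in [0, 1)")
    rng = np.random.default_rng(config.seed)
    n_regions = config.n_clusters
    cpr = cells_per_region or config.cells_per_cluster_mc
    truth = GroundTruth()
    slices = []
    for s in range(n_slices):
        ids, xs, ys, regions = [], [], [], []
        for r in range(n_regions):
            x0 = r * (block_size + block_gap)
            xs.append(rng.uniform(x0, x0 + block_size, size=cpr))
            ys.append(rng.uniform(0, block_size, size=cpr))
            regions.extend([f"region{r}"] * cpr)
            ids.extend([f"s{s}_r{r}_c{i}" for i in range(cpr)])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        regions = np.array(regions, dtype=object)
        ids = np.array(ids)

        labels = regions.copy()
        n_flip = int(round(noise_rate * len(ids)))
        if n_flip:
            flip = rng.choice(len(ids), size=n_flip, replace=False)
            all_regions = [f"region{r}" for r in range(n_regions)]
            for i in flip:
                others = [r for r in all_regions if r != regions[i]]
                labels[i] = others[rng.integers(len(others))]
        for cid, r in zip(ids, regions):
            truth.spatial_truth[cid] = r
        slices.append(
            SpatialSlice(
                cell_ids=ids, x=x, y=y, slice_id=f"slice{s}", initial_labels=labels
            )
        )
    return slices, truth


def simulate_motif_regions(
    n_dmrs: int,
    motif: MotifPwm,
    planted_fraction: float,
    seed: int,
    region_length: int = 200,
) -> tuple[pd.DataFrame, list[str]]:
    """DMR intervals with i.i.d. background sequences, a fraction of which
    carry one sampled motif instance.

    Returns (records, sequences); records columns: dmr_id, chrom, start, end,
    planted.  With 0 < planted_fraction * n_dmrs < 1, one instance is planted
    (with a warning) so the foreground is never silently empty.
    """
    if motif.width > region_length:
        raise ValueError("motif width exceeds region length")
    rng = np.random.default_rng(seed)
    n_planted = int(round(planted_fraction * n_dmrs))
    if planted_fraction > 0 and n_planted < 1:
        warnings.warn("planted_fraction * n_dmrs < 1; planting one instance")
        n_planted = 1
    planted_idx = set(rng.choice(n_dmrs, size=n_planted, replace=False).tolist())

    bases = np.array(list("ACGT"))
    sequences, rows = [], []
    for i in range(n_dmrs):
        seq = "".join(rng.choice(bases, size=region_length))
        if i in planted_idx:
            site = motif.sample_site(rng, min_score=motif_hit_threshold(motif))
            pos = int(rng.integers(0, region_length - motif.width + 1))
            seq = seq[:pos] + site + seq[pos + motif.width :]
        sequences.append(seq)
        start = i * 10_000
        rows.append((f"dmr{i}", "chr1", start, start + region_length, i in planted_idx))
    records = pd.DataFrame(rows, columns=["dmr_id", "chrom", "start", "end", "planted"])
    return records, sequences


def simulate_grn_profiles(
    n_clusters: int = 30,
    n_tfs: int = 10,
    n_genes: int = 60,
    n_dmrs: int = 80,
    n_triplets: int = 10,
    noise: float = 0.25,
    motif_width: int = 8,
    region_length: int = 200,
    seed: int = 0,
) -> dict:
    """Cluster-level profiles with planted TF -> DMR -> target cascades.

    For each planted triplet a latent per-cluster activity drives the TF's
    expression and the target's expression up and the DMR's mCG down; all
    other profiles are independent noise.  Each TF has a near-deterministic
    PWM; planted triplet DMR sequences carry that TF's motif and sit within
    1 Mb of the target's TSS, while unplanted DMRs are placed far away.

    Returns a dict with keys: tf_expr, gene_expr, dmr_mcg (DataFrames,
    feature x cluster), dmr_records, sequences, motifs, tss, triplets (list of
    (tf, dmr_id, gene) ground truth).
    """
    if n_triplets > min(n_tfs, n_genes, n_dmrs):
        raise ValueError("n_triplets must not exceed any node pool")
    rng = np.random.default_rng(seed)
    clusters = [f"c{j}" for j in range(n_clusters)]
    tfs = [f"tf{i}" for i in range(n_tfs)]
    genes = [f"g{i}" for i in range(n_genes)]
    dmr_ids = [f"dmr{i}" for i in range(n_dmrs)]

    tf_expr = pd.DataFrame(
        rng.normal(1.0, 1.0, size=(n_tfs, n_clusters)).clip(min=0.0),
        index=tfs, columns=clusters,
    )
    gene_expr = pd.DataFrame(
        rng.normal(1.0, 1.0, size=(n_genes, n_clusters)).clip(min=0.0),
        index=genes, columns=clusters,
    )
    dmr_mcg = pd.DataFrame(
        rng.beta(8.0, 2.0, size=(n_dmrs, n_clusters)), index=dmr_ids, columns=clusters
    )

    # TF motifs: sharp consensus PWMs
    bases = "ACGT"
    motifs = []
    for tf in tfs:
        consensus = rng.integers(0, 4, size=motif_width)
        mat = np.full((motif_width, 4), 0.02)
        mat[np.arange(motif_width), consensus] = 0.94
        motifs.append(MotifPwm(f"motif_{tf}", mat, tf_genes=(tf,)))

    tss = {g: 2_000_000 + i * 3_000_000 for i, g in enumerate(genes)}
    # default DMR positions: far from every TSS (> 1 Mb)
    dmr_pos = {d: 1_500_000 + i * 3_000_000 for i, d in enumerate(dmr_ids)}

    bases_arr = np.array(list(bases))
    sequences = ["".join(rng.choice(bases_arr, size=region_length)) for _ in dmr_ids]

    triplets = []
    for t in range(n_triplets):
        tf, gene, dmr = tfs[t], genes[t], dmr_ids[t]
        activity = rng.normal(0.0, 1.0, size=n_clusters)
        tf_expr.loc[tf] = np.clip(
            1.5 + activity + rng.normal(0, noise, n_clusters), 0.0, None
        )
        gene_expr.loc[gene] = np.clip(
            1.5 + activity + rng.normal(0, noise, n_clusters), 0.0, None
        )
        z = -activity + rng.normal(0, noise, n_clusters)
        dmr_mcg.loc[dmr] = 1.0 / (1.0 + np.exp(-z))  # active TF -> hypomethylated DMR
        # place the DMR next to the target TSS and plant the TF's motif
        dmr_pos[dmr] = tss[gene] + int(rng.integers(-500_000, 500_000))
        site = motifs[t].sample_site(rng, min_score=motif_hit_threshold(motifs[t]))
        pos = int(rng.integers(0, region_length - motif_width + 1))
        seq = sequences[t]
        sequences[t] = seq[:pos] + site + seq[pos + motif_width :]
        triplets.append((tf, dmr, gene))

    dmr_records = pd.DataFrame(
        {
            "dmr_id": dmr_ids,
            "chrom": "chr1",
            "start": [dmr_pos[d] - region_length // 2 for d in dmr_ids],
            "end": [dmr_pos[d] + region_length // 2 for d in dmr_ids],
        }
    )
    return dict(
        tf_expr=tf_expr,
        gene_expr=gene_expr,
        dmr_mcg=dmr_mcg,
        dmr_records=dmr_records,
        sequences=sequences,
        motifs=motifs,
        tss=tss,
        triplets=triplets,
    )
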