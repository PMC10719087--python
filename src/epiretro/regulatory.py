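"""Regulatory layers: DEGs, pseudobulk methylation, hypo-DMR assignment,
recovery-curve motif enrichment, shuffle-FDR DMR-gene association, and GRN
triplet assembly.

The regulatory model treats DMRs (differentially methylated regions, intervals
with cluster-variable CG methylation) as putative enhancers.  A DMR is a
hypo-DMR of a cluster when its mCG there falls below the 10th quantile of all
DMR values in the region group AND below the 10th quantile of that DMR's
values across clusters.  Motif enrichment in a cluster's hypo-DMR set uses the
recovery-curve statistic: DMRs ranked by motif score, the curve tracks the
fraction of the hypo-set recovered at each rank up to a top fraction of the
ranking, the AUC is the mean recovery, and the NES is the AUC z-scored against
all other motifs in the collection (enriched: AUC > 0.01 and NES > 3).
Edges between TFs, DMRs and target genes are Pearson correlations across
cluster pseudobulk profiles, gated by an empirical FDR from within-cluster
value shuffles; a triplet requires all three edges, a motif hit of the TF in
the DMR, and the DMR within 1 Mb of the target's TSS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .motifs import MotifPwm, motif_hit_threshold, scan_sequences

logger = logging.getLogger(__name__)

__all__ = [
    "GrnTriplet",
    "MotifEnrichmentResult",
    "pairwise_degs",
    "pseudobulk_by_cluster",
    "assign_hypo_dmrs",
    "motif_enrichment",
    "expressed_tf_filter",
    "quantile_normalize_within_cluster",
    "shuffle_fdr_edges",
    "dmr_gene_association",
    "build_grn",
]


@dataclass
class GrnTriplet:
    tf: str
    dmr: str
    target: str
    pcc_tf_dmr: float
    pcc_tf_target: float
    pcc_dmr_target: float
    motif_hit: bool
    tss_distance: int


@dataclass
class MotifEnrichmentResult:
    """Recovery-curve AUC, NES and enriched flags, motif x cluster."""

    auc: pd.DataFrame
    nes: pd.DataFrame
    enriched: pd.DataFrame

    def enriched_motifs(self, cluster) -> list[str]:
        col = self.enriched[cluster]
        return list(col.index[col])


# ---------------------------------------------------------------------------
# DEGs and pseudobulk
# ---------------------------------------------------------------------------

def pairwise_degs(
    expr: pd.DataFrame,
    clusters: np.ndarray,
    lfc_min: float = 1.0,
    fdr_max: float = 0.01,
    top_n: int = 100,
    min_cells: int = 10,
    pseudocount: float = 0.01,
) -> tuple[set, dict]:
    """Pairwise differentially expressed genes between clusters.

    ``expr`` is cell-by-gene log1p-normalized expression.  Per cluster pair:
    two-sided Wilcoxon rank-sum per gene, BH across genes; fold change is the
    ratio of mean linear-scale normalized expression (ratios need the linear
    scale) with ``pseudocount`` added to both means.  Genes pass with
    |log2 FC| > ``lfc_min`` and FDR < ``fdr_max``; at most ``top_n`` are kept
    per pair, ranked by FDR then |log2 FC|.  Returns (union, per-pair frames).
    """
    clusters = np.asarray(clusters)
    genes = expr.columns.to_numpy()
    linear = np.expm1(expr.to_numpy(dtype=float))
    logvals = expr.to_numpy(dtype=float)
    uniq = [c for c in np.unique(clusters) if (clusters == c).sum() >= min_cells]
    skipped = set(np.unique(clusters)) - set(uniq)
    if skipped:
        logger.warning("clusters below %d cells skipped: %s", min_cells, sorted(skipped))

    union: set = set()
    per_pair: dict = {}
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            xa, xb = logvals[clusters == a], logvals[clusters == b]
            la, lb = linear[clusters == a], linear[clusters == b]
            res = stats.mannwhitneyu(xa, xb, axis=0, method="asymptotic")
            fdr = multipletests(res.pvalue, method="fdr_bh")[1]
            lfc = np.log2(
                (lb.mean(axis=0) + pseudocount) / (la.mean(axis=0) + pseudocount)
            )
            mask = (fdr < fdr_max) & (np.abs(lfc) > lfc_min)
            tab = pd.DataFrame(
                {"gene": genes[mask], "log2fc": lfc[mask], "fdr": fdr[mask]}
            ).sort_values(
                ["fdr", "log2fc"],
                key=lambda s: s if s.name == "fdr" else -s.abs(),
                kind="mergesort",
            )
            if len(tab) > top_n:
                tab = tab.iloc[:top_n]
            per_pair[(a, b)] = tab.reset_index(drop=True)
            union |= set(tab["gene"])
    return union, per_pair


def pseudobulk_by_cluster(
    mc: np.ndarray,
    cov: np.ndarray,
    clusters: np.ndarray,
    feature_ids: np.ndarray,
    min_cells: int = 30,
) -> pd.DataFrame:
    """Cluster-by-feature pooled methylation fraction sum(mc)/sum(cov).

    Clusters with fewer than ``min_cells`` cells are excluded; features with
    zero pooled coverage in a cluster are NaN.
    """
    clusters = np.asarray(clusters)
    rows = {}
    for c in np.unique(clusters):
        m = clusters == c
        if m.sum() < min_cells:
            logger.info("cluster %s has %d cells (< %d); excluded", c, m.sum(), min_cells)
            continue
        mc_sum = mc[m].sum(axis=0).astype(float)
        cov_sum = cov[m].sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rows[c] = np.where(cov_sum > 0, mc_sum / np.maximum(cov_sum, 1), np.nan)
    return pd.DataFrame(rows, index=feature_ids).T


# ---------------------------------------------------------------------------
# hypo-DMRs and motif enrichment
# ---------------------------------------------------------------------------

def assign_hypo_dmrs(dmr_mcg: pd.DataFrame, q: float = 0.10) -> pd.DataFrame:
    """Hypo-DMR flags (DMR-by-cluster boolean).

    ``dmr_mcg`` rows are DMRs, columns clusters.  flag(d, c) is True iff the
    value is strictly below the q-quantile of all values in the matrix AND
    strictly below the q-quantile of DMR d's values across clusters
    (linear-interpolation quantiles; NaNs ignored).
    """
    if dmr_mcg.shape[1] < 2:
        raise ValueError("need at least 2 clusters")
    vals = dmr_mcg.to_numpy(dtype=float)
    global_q = np.nanquantile(vals, q)
    row_q = np.nanquantile(vals, q, axis=1, keepdims=True)
    flags = (vals < global_q) & (vals < row_q)
    return pd.DataFrame(flags, index=dmr_mcg.index, columns=dmr_mcg.columns)


def recovery_auc(
    ranked_ids: np.ndarray, foreground: set, top: int
) -> float:
    """Mean fraction of ``foreground`` recovered over ranks 1..top of
    ``ranked_ids`` (the recovery-curve AUC)."""
    if not foreground:
        raise ValueError("foreground set is empty")
    hits = np.cumsum([rid in foreground for rid in ranked_ids[:top]])
    recovery = hits / len(foreground)
    if recovery.size < top:  # fewer items than the cutoff: curve is flat after
        recovery = np.concatenate(
            [recovery, np.full(top - recovery.size, recovery[-1] if recovery.size else 0.0)]
        )
    return float(recovery.mean())


def motif_enrichment(
    hypo_sets: dict,
    dmr_ids: np.ndarray,
    sequences: list[str],
    motifs: list[MotifPwm],
    auc_top_fraction: float = 0.05,
    auc_min: float = 0.01,
    nes_min: float = 3.0,
) -> MotifEnrichmentResult:
    """Recovery-curve motif enrichment per cluster.

    For each motif, every DMR sequence is scored (max log-odds over positions
    and strands); DMRs are ranked by descending score with ties broken by DMR
    id.  With N DMRs and T = ceil(auc_top_fraction * N), the AUC is the mean
    recovered fraction of the cluster's hypo-set over ranks 1..T, and the NES
    is the AUC z-scored across the motif collection within the cluster.
    Clusters with empty hypo-sets are skipped.
    """
    if len(motifs) < 10:
        logger.warning("NES is unstable with < 10 motifs (got %d)", len(motifs))
    dmr_ids = np.asarray(dmr_ids)
    n = len(dmr_ids)
    top = math.ceil(auc_top_fraction * n)

    rankings = {}
    for motif in motifs:
        scores = scan_sequences(motif, sequences)
        order = np.lexsort((dmr_ids, -scores))
        rankings[motif.motif_id] = dmr_ids[order]

    clusters = [c for c, s in hypo_sets.items() if len(s) > 0]
    skipped = set(hypo_sets) - set(clusters)
    if skipped:
        logger.info("clusters with empty hypo-sets skipped: %s", sorted(skipped))

    auc = pd.DataFrame(index=[m.motif_id for m in motifs], columns=clusters, dtype=float)
    for c in clusters:
        fg = set(hypo_sets[c])
        for mid, ranked in rankings.items():
            auc.loc[mid, c] = recovery_auc(ranked, fg, top)
    mean = auc.mean(axis=0)
    sd = auc.std(axis=0, ddof=0).replace(0, np.nan)
    nes = (auc - mean) / sd
    enriched = (auc > auc_min) & (nes > nes_min)
    return MotifEnrichmentResult(auc=auc, nes=nes.fillna(0.0), enriched=enriched.fillna(False))


def expressed_tf_filter(
    enrichment: MotifEnrichmentResult,
    motifs: list[MotifPwm],
    tf_expr: pd.DataFrame,
    tf_mch_norm: pd.DataFrame,
) -> dict:
    """Keep TFs plausibly active where their motif is enriched.

    A TF annotated on an enriched motif is kept for a cluster when its
    expression there is > 0 and its normalized gene-body mCH is < 1 in at
    least one cluster where the motif is enriched.  ``tf_expr`` and
    ``tf_mch_norm`` are TF-by-cluster frames.  Returns cluster -> TF set.
    """
    tf_of_motif = {m.motif_id: m.tf_genes for m in motifs}
    out: dict = {c: set() for c in enrichment.enriched.columns}
    for c in enrichment.enriched.columns:
        for mid in enrichment.enriched_motifs(c):
            for tf in tf_of_motif.get(mid, ()):  # motifs may annotate several TFs
                if tf not in tf_expr.index or tf not in tf_mch_norm.index:
                    logger.info("TF %s absent from expression panel; dropped", tf)
                    continue
                if tf_expr.loc[tf, c] > 0 and tf_mch_norm.loc[tf, c] < 1:
                    out[c].add(tf)
    return out


# ---------------------------------------------------------------------------
# correlations with shuffle FDR
# ---------------------------------------------------------------------------

def quantile_normalize_within_cluster(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across features within each cluster (column):
    every column gets the mean sorted profile, ties averaged."""
    vals = df.to_numpy(dtype=float)
    order = np.sort(vals, axis=0)
    reference = order.mean(axis=1)
    ranks = pd.DataFrame(vals).rank(axis=0, method="average").to_numpy() - 1.0
    lo = np.floor(ranks).astype(int)
    hi = np.ceil(ranks).astype(int)
    out = (reference[lo] + reference[hi]) / 2.0
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def _row_standardize(vals: np.ndarray) -> np.ndarray:
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (vals - mean) / sd
    z[sd[:, 0] == 0] = np.nan  # constant vectors excluded from correlation
    return z


def shuffle_fdr_edges(
    a: pd.DataFrame,
    b: pd.DataFrame,
    pairs: list[tuple[int, int]],
    n_shuffles: int = 100,
    fdr: float = 0.01,
    seed: int = 0,
    sign: str = "positive",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical shuffle-FDR gate on Pearson correlations across clusters.

    ``a`` and ``b`` are feature-by-cluster frames sharing columns; ``pairs``
    index rows of a and b.  The null permutes feature values independently
    within each cluster (column) of both matrices, ``n_shuffles`` times, and
    recomputes the statistic for the same pairs.  At candidate threshold t,
    FDR(t) = (mean null exceedances) / (observed exceedances); edges at or
    above the smallest observed t with FDR < ``fdr`` are significant.

    ``sign``: "positive" gates on the PCC itself; "two_sided" on |PCC|.
    Returns (pcc per pair, significance mask, threshold or inf when nothing
    passes).
    """
    if list(a.columns) != list(b.columns):
        raise ValueError("frames must share cluster columns")
    if a.shape[1] < 3:
        raise ValueError("PCC across clusters needs >= 3 clusters")
    rng = np.random.default_rng(seed)
    pairs_arr = np.asarray(pairs, dtype=int).reshape(-1, 2)
    n_clusters = a.shape[1]

    za = _row_standardize(a.to_numpy(dtype=float))
    zb = _row_standardize(b.to_numpy(dtype=float))

    def _pcc(za_, zb_):
        return (za_[pairs_arr[:, 0]] * zb_[pairs_arr[:, 1]]).sum(axis=1) / n_clusters

    pcc = _pcc(za, zb)
    stat = pcc if sign == "positive" else np.abs(pcc)

    null_stats = []
    av, bv = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    for _ in range(n_shuffles):
        pa = np.empty_like(av)
        pb = np.empty_like(bv)
        for j in range(n_clusters):
            pa[:, j] = av[rng.permutation(av.shape[0]), j]
            pb[:, j] = bv[rng.permutation(bv.shape[0]), j]
        npcc = _pcc(_row_standardize(pa), _row_standardize(pb))
        null_stats.append(npcc if sign == "positive" else np.abs(npcc))
    null = np.sort(np.concatenate(null_stats)) if null_stats else np.array([])

    finite = np.isfinite(stat)
    obs_sorted = np.sort(stat[finite])
    threshold = np.inf
    for t in obs_sorted:  # ascending: first t controlling FDR is the loosest
        n_obs = len(obs_sorted) - np.searchsorted(obs_sorted, t, side="left")
        n_null = (len(null) - np.searchsorted(null, t, side="left")) / max(n_shuffles, 1)
        if n_obs > 0 and n_null / n_obs < fdr:
            threshold = t
            break
    sig = finite & (stat >= threshold)
    return pcc, sig, threshold


def dmr_gene_association(
    dmr_mcg: pd.DataFrame,
    gene_mch: pd.DataFrame,
    dmr_mid: dict,
    tss: dict,
    window: float = 1e6,
    fdr: float = 0.01,
    n_shuffles: int = 100,
    seed: int = 0,
    sign: str = "positive",
) -> pd.DataFrame:
    """DMR-gene edges: within-window pairs with shuffle-FDR-significant PCC
    between DMR mCG and gene-body mCH across clusters.

    Both frames are feature-by-cluster.  Candidate pairs have
    |DMR midpoint - gene TSS| <= ``window``.  Default ``sign='positive'``
    keeps co-repression edges (mCG and mCH rising together); ``'two_sided'``
    keeps any significant correlation.
    """
    dmr_ids = dmr_mcg.index.to_numpy()
    gene_ids = gene_mch.index.to_numpy()
    pairs, meta = [], []
    for i, d in enumerate(dmr_ids):
        for j, g in enumerate(gene_ids):
            dist = abs(dmr_mid[d] - tss[g])
            if dist <= window:
                pairs.append((i, j))
                meta.append((d, g, int(dist)))
    if not pairs:
        logger.warning("no DMR-gene candidates within %g bp", window)
        return pd.DataFrame(columns=["dmr", "gene", "distance", "pcc", "significant"])
    pcc, sig, _ = shuffle_fdr_edges(
        dmr_mcg, gene_mch, pairs, n_shuffles=n_shuffles, fdr=fdr, seed=seed, sign=sign
    )
    out = pd.DataFrame(meta, columns=["dmr", "gene", "distance"])
    out["pcc"] = pcc
    out["significant"] = sig
    return out


def build_grn(
    tf_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    dmr_mcg: pd.DataFrame,
    sequences: list[str],
    motifs: list[MotifPwm],
    dmr_mid: dict,
    tss: dict,
    enriched_tfs: set,
    deg_union: set,
    window: float = 1e6,
    fdr: float = 0.01,
    n_shuffles: int = 100,
    seed: int = 0,
) -> list[GrnTriplet]:
    """Assemble TF - DMR - target triplets.

    Only motif-enriched TFs and DEG-union targets enter.  All matrices are
    quantile normalized within each cluster across features (expression
    matrices jointly, mCG separately).  The three edge families are each gated
    by shuffle-FDR < ``fdr`` on two-sided PCC across clusters; TF-DMR edges
    additionally require a predicted binding site of the TF's motif in the DMR
    sequence, and DMR-gene edges require the DMR within ``window`` of the
    target TSS.  A triplet is emitted when all three edges hold.
    """
    tfs = [t for t in tf_expr.index if t in enriched_tfs]
    targets = [g for g in gene_expr.index if g in deg_union]
    if not tfs or not targets:
        logger.warning("no eligible TFs or targets; empty GRN")
        return []
    dmr_ids = list(dmr_mcg.index)

    expr_all = pd.concat([tf_expr.loc[tfs], gene_expr.loc[targets]])
    expr_qn = quantile_normalize_within_cluster(expr_all)
    mcg_qn = quantile_normalize_within_cluster(dmr_mcg)
    tf_qn = expr_qn.loc[tfs]
    gene_qn = expr_qn.loc[targets]

    # motif hits: TF has a binding site in the DMR
    motif_by_tf: dict = {}
    for m in motifs:
        for tf in m.tf_genes:
            motif_by_tf.setdefault(tf, []).append(m)
    hit = np.zeros((len(tfs), len(dmr_ids)), dtype=bool)
    for ti, tf in enumerate(tfs):
        for m in motif_by_tf.get(tf, []):
            scores = scan_sequences(m, sequences)
            hit[ti] |= scores >= motif_hit_threshold(m)

    # TF-DMR edges (gated on motif hits)
    td_pairs = [(i, j) for i in range(len(tfs)) for j in range(len(dmr_ids)) if hit[i, j]]
    td_edges: dict = {}
    if td_pairs:
        pcc, sig, _ = shuffle_fdr_edges(
            tf_qn, mcg_qn, td_pairs, n_shuffles, fdr, seed, sign="two_sided"
        )
        for (i, j), r, s in zip(td_pairs, pcc, sig):
            if s:
                td_edges[(tfs[i], dmr_ids[j])] = r

    # TF-gene edges
    tg_pairs = [
        (i, j) for i in range(len(tfs)) for j in range(len(targets))
        if tfs[i] != targets[j]
    ]
    tg_edges: dict = {}
    pcc, sig, _ = shuffle_fdr_edges(
        tf_qn, gene_qn, tg_pairs, n_shuffles, fdr, seed + 1, sign="two_sided"
    )
    for (i, j), r, s in zip(tg_pairs, pcc, sig):
        if s:
            tg_edges[(tfs[i], targets[j])] = r

    # DMR-gene edges (window-gated, vs target expression)
    dg_pairs, dg_meta = [], []
    for i, d in enumerate(dmr_ids):
        for j, g in enumerate(targets):
            if abs(dmr_mid[d] - tss[g]) <= window:
                dg_pairs.append((i, j))
                dg_meta.append((d, g))
    dg_edges: dict = {}
    if dg_pairs:
        pcc, sig, _ = shuffle_fdr_edges(
            mcg_qn, gene_qn, dg_pairs, n_shuffles, fdr, seed + 2, sign="two_sided"
        )
        for (d, g), r, s in zip(dg_meta, pcc, sig):
            if s:
                dg_edges[(d, g)] = r

    triplets = []
    for (tf, dmr), r_td in td_edges.items():
        for (d, g), r_dg in dg_edges.items():
            if d != dmr:
                continue
            r_tg = tg_edges.get((tf, g))
            if r_tg is None:
                continue
            triplets.append(
                GrnTriplet(
                    tf=tf, dmr=dmr, target=g,
                    pcc_tf_dmr=float(r_td),
                    pcc_tf_target=float(r_tg),
                    pcc_dmr_target=float(r_dg),
                    motif_hit=True,
                    tss_distance=int(abs(dmr_mid[dmr] - tss[g])),
                )
            )
    if not triplets:
        logger.info("no triplets passed all gates")
    return triplets
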