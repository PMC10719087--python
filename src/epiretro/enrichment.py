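"""Projection-enriched co-clusters, sex-difference tests and
neurotransmitter marker summaries.

For each projection target within a source, the proportion of its neurons in
each joint cluster is computed; clusters holding >5% of a projection's cells
are associated with it.  A one-sided Fisher exact test (odds ratio > 1) asks
whether the projection is over-represented in the cluster relative to all
other projections, BH-corrected across (cluster, target) pairs.  Displayed
values are the proportions z-scored within each cluster across targets.
Sex differences use two-sided Fisher tests per cluster, BH across clusters.
The quantification uses absolute proportions rather than ratios to unbiased
data (a relative mode exists but is off by default): unbiased reference
profiling amplifies small dissections, distorting relative proportions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["enrichment_table", "sex_difference_test", "neurotransmitter_profile"]


def enrichment_table(
    clusters: np.ndarray,
    targets: np.ndarray,
    assoc_threshold: float = 0.05,
    fdr_threshold: float = 0.01,
    reference_clusters: np.ndarray | None = None,
) -> pd.DataFrame:
    """Long-format enrichment table over (cluster, target) pairs.

    Columns: cluster, target, n_cells, proportion (of the target's cells in
    the cluster; sums to 1 over clusters per target), associated (proportion >
    threshold), odds_ratio, p_value (one-sided Fisher, OR > 1), fdr (BH over
    all pairs), zscore (proportion z-scored within cluster across targets),
    enriched (fdr < threshold).  Targets with fewer than 2 cells are excluded.
    ``reference_clusters`` switches on the relative mode: proportions are
    divided by the unbiased reference cluster proportions before z-scoring.
    """
    clusters = np.asarray(clusters)
    targets = np.asarray(targets)
    uniq_t = []
    for t in np.unique(targets):
        if (targets == t).sum() < 2:
            logger.warning("target %s has < 2 cells; excluded", t)
        else:
            uniq_t.append(t)
    uniq_c = np.unique(clusters)

    counts = (
        pd.crosstab(pd.Series(clusters, name="cluster"), pd.Series(targets, name="target"))
        .reindex(index=uniq_c, columns=uniq_t, fill_value=0)
        .astype(int)
    )
    totals = counts.sum(axis=0)
    prop = counts / totals

    if reference_clusters is not None:
        ref = pd.Series(reference_clusters).value_counts(normalize=True)
        ref = ref.reindex(uniq_c).fillna(np.nan)
        prop = prop.div(ref, axis=0)

    rows = []
    n_all = counts.to_numpy().sum()
    for c in uniq_c:
        for t in uniq_t:
            a = int(counts.loc[c, t])                       # this target, in cluster
            b = int(totals[t] - a)                          # this target, out
            cc = int(counts.loc[c].sum() - a)               # other targets, in
            d = int(n_all - totals[t] - cc)                 # other targets, out
            odds, p = stats.fisher_exact([[a, b], [cc, d]], alternative="greater")
            rows.append(
                dict(cluster=c, target=t, n_cells=a,
                     proportion=float(prop.loc[c, t]),
                     associated=bool(prop.loc[c, t] > assoc_threshold),
                     odds_ratio=float(odds), p_value=float(p))
            )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["enriched"] = out["fdr"] < fdr_threshold

    # z-score within cluster across targets
    zs = {}
    degenerate = len(uniq_t) < 2
    for c in uniq_c:
        vals = prop.loc[c].to_numpy(dtype=float)
        sd = vals.std(ddof=0)
        if degenerate or sd == 0:
            zs[c] = np.zeros(len(uniq_t))
        else:
            zs[c] = (vals - vals.mean()) / sd
    out["zscore"] = [
        zs[r.cluster][uniq_t.index(r.target)] for r in out.itertuples()
    ]
    out["zscore_degenerate"] = degenerate
    return out


def sex_difference_test(
    clusters: np.ndarray,
    sex: np.ndarray,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Two-sided Fisher per cluster on male/female membership, BH across
    clusters.  Raises when only one sex is present (the projection should be
    skipped upstream in that case)."""
    clusters = np.asarray(clusters)
    sex = np.asarray(sex)
    sexes = np.unique(sex)
    if len(sexes) < 2:
        raise ValueError("both sexes must be present")
    s0 = sexes[0]
    n0 = int((sex == s0).sum())
    n1 = int(len(sex) - n0)
    rows = []
    for c in np.unique(clusters):
        in_c = clusters == c
        a = int((in_c & (sex == s0)).sum())
        b = n0 - a
        cc = int(in_c.sum() - a)
        d = n1 - cc
        odds, p = stats.fisher_exact([[a, b], [cc, d]], alternative="two-sided")
        rows.append(dict(cluster=c, n_sex_a=a, n_sex_b=cc,
                         odds_ratio=float(odds), p_value=float(p)))
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def neurotransmitter_profile(
    expr: pd.DataFrame,
    mch: pd.DataFrame,
    expr_clusters: np.ndarray,
    mch_clusters: np.ndarray,
    marker_genes: list[str],
    mch_floor: float = 1e-3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster neurotransmitter marker usage.

    Returns (mean normalized expression per cluster x marker, per-cell
    reciprocal gene-body mCH table for the markers).  Reciprocal mCH is
    1 / max(level, ``mch_floor``): hypomethylated (actively used) markers give
    high values.  Missing markers yield NaN columns and a log message.
    """
    expr_clusters = np.asarray(expr_clusters)
    mch_clusters = np.asarray(mch_clusters)
    uniq = np.unique(expr_clusters)

    expr_out = pd.DataFrame(index=uniq, columns=marker_genes, dtype=float)
    for g in marker_genes:
        if g not in expr.columns:
            logger.warning("marker %s absent from expression panel", g)
            continue
        for c in uniq:
            expr_out.loc[c, g] = float(expr.loc[expr_clusters == c, g].mean())

    recip = pd.DataFrame(index=mch.index, columns=marker_genes, dtype=float)
    recip["cluster"] = mch_clusters
    for g in marker_genes:
        if g not in mch.columns:
            logger.warning("marker %s absent from methylation panel", g)
            continue
        recip[g] = 1.0 / np.maximum(mch[g].to_numpy(dtype=float), mch_floor)
    return expr_out, recip


def compare_marker_groups(
    recip: pd.DataFrame, marker: str, group_a: list, group_b: list
) -> float:
    """Two-sided rank-sum p value comparing reciprocal mCH of one marker
    between two groups of clusters."""
    a = recip.loc[recip["cluster"].isin(group_a), marker].dropna()
    b = recip.loc[recip["cluster"].isin(group_b), marker].dropna()
    return float(stats.ranksums(a, b).pvalue)
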