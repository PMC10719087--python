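"""Pairwise projection-target discriminability by penalized logistic AUROC.

For two groups of projection-labelled cells from the same source, an L2
logistic regression on coverage-filtered gene-body posterior mCH predicts the
group label; the test AUROC measures how epigenetically distinguishable the
two targets are.  Computational replicates split each class 50/50 at random
(50 seeds, mean AUROC reported); biological replicates train on one sex and
test on the other, averaging both directions.  Cross-source transfer fits on
one source region and evaluates on another.  Gene-category analysis compares
the predictive power of functionally defined gene sets, downsampling larger
categories to the size of smaller ones, with paired two-sided Wilcoxon
signed-rank tests across comparisons (BH-corrected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AurocResult",
    "pairwise_projection_auroc",
    "cross_source_auroc",
    "gene_category_auroc",
    "identify_dmgs",
]

MIN_CELLS_PER_CLASS = 10


@dataclass
class AurocResult:
    source: str
    pair: tuple[str, str]
    feature_set: str
    split: str                       # "computational" | "biological"
    auroc_values: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_auroc: float = np.nan
    n_per_class: tuple[int, int] = (0, 0)
    available: bool = True


def _logistic() -> LogisticRegression:
    # L2 penalty, C=1, deterministic solver; features are bounded posterior
    # levels so no standardization is applied
    return LogisticRegression(C=1.0, solver="liblinear", max_iter=200)


def _fit_auroc(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray, y_test: np.ndarray
) -> float:
    model = _logistic().fit(x_train, y_train)
    return float(roc_auc_score(y_test, model.decision_function(x_test)))


def pairwise_projection_auroc(
    features: np.ndarray,
    labels: np.ndarray,
    pair: tuple[str, str],
    source: str = "source0",
    n_seeds: int = 50,
    split: str = "computational",
    sex: np.ndarray | None = None,
    min_cells: int = MIN_CELLS_PER_CLASS,
    seed: int = 0,
    feature_set: str = "gene_mch",
) -> AurocResult:
    """AUROC for one target pair.

    ``features``: cell-by-gene posterior mCH (already coverage-filtered);
    ``labels``: projection target per cell.  Computational mode runs
    ``n_seeds`` stratified half/half splits (seeded from ``seed``) and reports
    the mean; biological mode trains on one sex and tests on the other, both
    directions averaged, and is marked unavailable when a sex is missing.
    """
    labels = np.asarray(labels)
    mask = np.isin(labels, pair)
    x = np.asarray(features, float)[mask]
    y = (labels[mask] == pair[1]).astype(int)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if min(n0, n1) < min_cells:
        raise ValueError(
            f"both classes need >= {min_cells} cells (got {n0}, {n1})"
        )

    if split == "computational":
        vals = np.empty(n_seeds)
        for i in range(n_seeds):
            xtr, xte, ytr, yte = train_test_split(
                x, y, test_size=0.5, stratify=y, random_state=seed + i
            )
            vals[i] = _fit_auroc(xtr, ytr, xte, yte)
        return AurocResult(
            source, pair, feature_set, split, vals, float(vals.mean()), (n0, n1)
        )
    if split == "biological":
        if sex is None:
            raise ValueError("biological mode requires per-cell sex labels")
        sx = np.asarray(sex)[mask]
        sexes = np.unique(sx)
        by_sex_ok = all(
            min((y[sx == s] == 0).sum(), (y[sx == s] == 1).sum()) >= 1 for s in sexes
        )
        if len(sexes) < 2 or not by_sex_ok:
            return AurocResult(
                source, pair, feature_set, split, np.array([]), np.nan, (n0, n1),
                available=False,
            )
        vals = []
        for train_sex in sexes[:2]:
            tr = sx == train_sex
            vals.append(_fit_auroc(x[tr], y[tr], x[~tr], y[~tr]))
        vals = np.array(vals)
        return AurocResult(
            source, pair, feature_set, split, vals, float(vals.mean()), (n0, n1)
        )
    raise ValueError(f"unknown split mode {split!r}")


def cross_source_auroc(
    features: np.ndarray,
    class_labels: np.ndarray,
    sources: np.ndarray,
    train_source: str,
    test_source: str,
    classes: tuple[str, str] = ("ET", "IT"),
    n_seeds: int = 50,
    seed: int = 0,
) -> float | None:
    """Train the two-class model on one source region, test on another.

    Diagonal entries (train == test) reduce to the within-source computational
    result.  Returns None when either source is missing a class.
    """
    class_labels = np.asarray(class_labels)
    sources = np.asarray(sources)
    x = np.asarray(features, float)

    def _mask(src):
        m = (sources == src) & np.isin(class_labels, classes)
        y = (class_labels[m] == classes[1]).astype(int)
        return m, y

    m_tr, y_tr = _mask(train_source)
    m_te, y_te = _mask(test_source)
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
        return None
    if train_source == test_source:
        res = pairwise_projection_auroc(
            x[m_tr], class_labels[m_tr], classes,
            source=train_source, n_seeds=n_seeds, seed=seed,
        )
        return res.mean_auroc
    return _fit_auroc(x[m_tr], y_tr, x[m_te], y_te)


def gene_category_auroc(
    features: pd.DataFrame,
    labels: np.ndarray,
    categories: dict[str, list[str]],
    comparisons: list[tuple[str, str]],
    n_seeds: int = 10,
    seed: int = 0,
    n_downsamples: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare predictive power of gene categories at matched sizes.

    Each category is intersected with the (coverage-filtered) feature columns.
    The tier size is the smallest category; larger categories are randomly
    downsampled (seeded) to the tier size, ``n_downsamples`` draws each, and
    the per-comparison AUROCs of the draws are averaged.  Category pairs are
    compared with two-sided Wilcoxon signed-rank over comparisons, BH across
    pairs.

    Returns (long results frame, paired-test frame).
    """
    rng = np.random.default_rng(seed)
    members = {
        name: [g for g in genes if g in features.columns]
        for name, genes in categories.items()
    }
    members = {k: v for k, v in members.items() if len(v) > 0}
    tier = min(len(v) for v in members.values())

    rows = []
    for name, genes in members.items():
        draws = (
            [list(genes)]
            if len(genes) == tier
            else [
                list(rng.choice(genes, size=tier, replace=False))
                for _ in range(n_downsamples)
            ]
        )
        for ci, pair in enumerate(comparisons):
            vals = []
            for subset in draws:
                res = pairwise_projection_auroc(
                    features[subset].to_numpy(), labels, pair,
                    n_seeds=n_seeds, seed=seed + ci,
                )
                vals.append(res.mean_auroc)
            rows.append(
                dict(category=name, comparison=f"{pair[0]}|{pair[1]}",
                     tier_size=tier, auroc=float(np.mean(vals)))
            )
    long = pd.DataFrame(rows)

    wide = long.pivot(index="comparison", columns="category", values="auroc")
    tests = []
    for a, b in combinations(sorted(members), 2):
        diff = wide[a] - wide[b]
        if np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(wide[a], wide[b], alternative="two-sided").pvalue)
        tests.append(dict(category_a=a, category_b=b,
                          median_diff=float(diff.median()), p_value=p))
    tests = pd.DataFrame(tests)
    if len(tests):
        tests["fdr"] = multipletests(tests["p_value"], method="fdr_bh")[1]
    return long, tests


def identify_dmgs(
    levels: pd.DataFrame,
    class_labels: np.ndarray,
    sources: np.ndarray,
    classes: tuple[str, str] = ("ET", "IT"),
    fdr_max: float = 0.01,
    min_fold: float = 1.25,
    pseudocount: float = 1e-3,
) -> tuple[set, pd.DataFrame]:
    """Differentially methylated genes between two classes, per source.

    Per source: two-sided rank-sum on posterior gene-body mCH per gene, BH
    across genes; a gene is a DMG when FDR < ``fdr_max`` and the mean mCH
    ratio exceeds ``min_fold`` in either direction.  The union over sources is
    returned with a source-by-DMG log2 fold-change matrix (class 2 over
    class 1; zero means floored at ``pseudocount``).
    """
    class_labels = np.asarray(class_labels)
    sources = np.asarray(sources)
    genes = levels.columns.to_numpy()
    union: set = set()
    fc_rows = {}
    for src in np.unique(sources):
        m = sources == src
        y = class_labels[m]
        x = levels.loc[m].to_numpy()
        a, b = x[y == classes[0]], x[y == classes[1]]
        if min(len(a), len(b)) < 2:
            logger.warning("source %s lacks cells in one class; skipped", src)
            continue
        _, pvals = stats.ranksums(a, b, axis=0)
        fdr = multipletests(pvals, method="fdr_bh")[1]
        ma = np.maximum(a.mean(axis=0), pseudocount)
        mb = np.maximum(b.mean(axis=0), pseudocount)
        lfc = np.log2(mb / ma)
        hits = (fdr < fdr_max) & (np.abs(lfc) > np.log2(min_fold))
        union |= set(genes[hits])
        fc_rows[src] = lfc
    fc = pd.DataFrame(fc_rows, index=genes).T
    dmgs = sorted(union)
    return set(dmgs), fc[dmgs] if dmgs else fc.iloc[:, :0]
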