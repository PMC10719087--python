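"""Core methylome containers and feature-level operations.

Single-nucleus methylome data arrive as two cell-by-feature count layers:
methylated basecalls ``mc`` and total basecalls ``cov``.  Features are either
100-kb genomic bins tiling the genome or gene bodies extended by a flank.
Because per-cell coverage of any one feature is shallow, raw fractions
``mc/cov`` are noisy; downstream analyses instead use posterior methylation
levels obtained by shrinking each fraction toward the cell's global mean under
a beta-binomial model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "MethylCountMatrix",
    "PosteriorLevels",
    "NormalizedExpression",
    "EmbeddingSpace",
    "make_genomic_bins",
    "extend_gene_bodies",
    "filter_autosomal",
    "posterior_methylation",
    "normalize_rna",
    "filter_features_by_coverage",
    "select_integration_features",
    "reduce_dimensions",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Ordered genomic features (0-based, half-open intervals).

    ``table`` columns: feature_id, chrom, start, end, kind, strand.
    """

    table: pd.DataFrame

    REQUIRED = ("feature_id", "chrom", "start", "end")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"FeatureSet missing column {col!r}")
        if (self.table["start"] >= self.table["end"]).any():
            raise ValueError("FeatureSet intervals must satisfy start < end")
        if self.table["feature_id"].duplicated().any():
            raise ValueError("duplicate feature ids")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["feature_id"].to_numpy()

    def sort_canonical(self) -> "FeatureSet":
        """Return a copy sorted by (chrom, start) — the canonical order."""
        t = self.table.sort_values(["chrom", "start"], kind="mergesort")
        return FeatureSet(t.reset_index(drop=True))

    def midpoints(self) -> np.ndarray:
        return ((self.table["start"] + self.table["end"]) // 2).to_numpy()


@dataclass
class MethylCountMatrix:
    """Cell-by-feature methylated (``mc``) and total (``cov``) basecall counts."""

    cells: np.ndarray
    features: FeatureSet
    mc: np.ndarray
    cov: np.ndarray
    context: str = "CH"

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        self.mc = np.asarray(self.mc)
        self.cov = np.asarray(self.cov)
        n, m = self.mc.shape
        if self.cov.shape != (n, m):
            raise ValueError("mc and cov shapes differ")
        if n != len(self.cells):
            raise ValueError("cell count mismatch")
        if m != len(self.features):
            raise ValueError("feature count mismatch")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell ids")
        if (self.mc > self.cov).any():
            raise ValueError("mc must be <= cov elementwise")
        if (self.mc < 0).any() or (self.cov < 0).any():
            raise ValueError("counts must be non-negative")
        if self.context not in {"CH", "CG", "CCC"}:
            raise ValueError(f"unknown context {self.context!r}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def subset_features(self, keep: np.ndarray) -> "MethylCountMatrix":
        """Subset to features whose ids appear in ``keep`` (order preserved)."""
        mask = np.isin(self.features.ids, np.asarray(keep))
        return MethylCountMatrix(
            self.cells,
            FeatureSet(self.features.table.loc[mask].reset_index(drop=True)),
            self.mc[:, mask],
            self.cov[:, mask],
            self.context,
        )

    def subset_cells(self, mask: np.ndarray) -> "MethylCountMatrix":
        mask = np.asarray(mask)
        return MethylCountMatrix(
            self.cells[mask], self.features, self.mc[mask], self.cov[mask], self.context
        )


@dataclass
class PosteriorLevels:
    """Posterior methylation fractions with the per-cell prior that produced them."""

    cells: np.ndarray
    feature_ids: np.ndarray
    levels: np.ndarray           # cell x feature, in [0, 1]
    prior_mean: np.ndarray       # mu per cell
    prior_strength: np.ndarray   # nu per cell

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.levels, index=self.cells, columns=self.feature_ids)


@dataclass
class NormalizedExpression:
    """log1p library-size-normalized expression; ``linear()`` recovers the scale
    on which fold changes are ratios of means."""

    cells: np.ndarray
    genes: np.ndarray
    values: np.ndarray  # cell x gene, ln(1 + count / total * mean_total)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cells, columns=self.genes)

    def linear(self) -> np.ndarray:
        return np.expm1(self.values)


@dataclass
class EmbeddingSpace:
    """A fitted linear reduction with out-of-sample transform.

    Coordinates are centred projections divided componentwise by the singular
    values, so every retained component of the fitting set has unit scale and
    no single component dominates neighbour search.
    """

    coords: np.ndarray
    singular_values: np.ndarray
    loadings: np.ndarray          # feature x component
    mean_: np.ndarray
    feature_ids: np.ndarray | None = None
    cells: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = self.singular_values
        if np.any(np.diff(s) > 1e-9):
            raise ValueError("singular values must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        X = np.asarray(matrix, dtype=float) - self.mean_
        return (X @ self.loadings) / self.singular_values


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def make_genomic_bins(chrom_sizes: dict[str, int], bin_size: int = 100_000) -> FeatureSet:
    """Tile each chromosome with non-overlapping half-open bins.

    The trailing partial bin is retained (``bedtools makewindows`` behaviour).
    Chromosomes of length 0 contribute no bins.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom in sorted(chrom_sizes):
        length = chrom_sizes[chrom]
        if length < 0:
            raise ValueError(f"negative length for {chrom}")
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            rows.append((f"{chrom}:{start}-{end}", chrom, start, end))
    table = pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end"])
    table["kind"] = "bin_100kb" if bin_size == 100_000 else f"bin_{bin_size}"
    table["strand"] = "."
    return FeatureSet(table)


def extend_gene_bodies(
    genes: FeatureSet,
    flank: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> FeatureSet:
    """Expand every gene body by ``flank`` bp on both sides.

    Starts are clipped at 0; ends are clipped at the chromosome length when
    chromosome sizes are known.  Feature ids are preserved.
    """
    t = genes.table.copy()
    t["start"] = np.maximum(t["start"] - flank, 0)
    t["end"] = t["end"] + flank
    if chrom_sizes is not None:
        limits = t["chrom"].map(chrom_sizes)
        known = limits.notna()
        t.loc[known, "end"] = np.minimum(
            t.loc[known, "end"], limits[known].astype(int)
        )
    t["kind"] = "gene_body_ext2kb" if flank == 2000 else f"gene_body_ext{flank}"
    return FeatureSet(t)


def filter_autosomal(features: FeatureSet, sex_chroms: set[str]) -> FeatureSet:
    """Drop features on sex chromosomes; input order is preserved."""
    mask = ~features.table["chrom"].isin(sex_chroms)
    if not mask.any():
        warnings.warn("no autosomal features remain after filtering")
    return FeatureSet(features.table.loc[mask].reset_index(drop=True))


# ---------------------------------------------------------------------------
# levels and normalization
# ---------------------------------------------------------------------------

def posterior_methylation(
    counts: MethylCountMatrix,
    coverage_weighted: bool = True,
) -> PosteriorLevels:
    """Beta-binomial posterior methylation levels, shrunk toward the cell mean.

    For each cell a Beta(alpha, beta) prior is fit with mean
    ``mu = sum(mc) / sum(cov)`` over its features and strength ``nu`` chosen by
    method of moments on the per-feature raw fractions: for a Beta with mean mu,
    ``var = mu (1 - mu) / (nu + 1)``, so ``nu = mu (1 - mu) / var - 1``.  The
    moment variance is coverage-weighted by default (``coverage_weighted=False``
    switches to unweighted moments).  When the moment estimate is degenerate
    (zero or negative variance, or nu <= 0) the prior strength falls back to 1.

    The posterior level is ``(mc + alpha) / (cov + alpha + beta)`` with
    ``alpha = mu nu`` and ``beta = (1 - mu) nu``.  Zero-coverage entries equal
    the cell's prior mean.  Cells with zero total coverage are excluded.
    """
    mc = counts.mc.astype(float)
    cov = counts.cov.astype(float)
    tot = cov.sum(axis=1)
    ok = tot > 0
    if not ok.all():
        logger.warning("excluding %d cells with zero total coverage", (~ok).sum())
    mc, cov, tot = mc[ok], cov[ok], tot[ok]
    cells = counts.cells[ok]

    mu = mc.sum(axis=1) / tot
    nu = np.ones(len(cells))
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(cov > 0, mc / np.maximum(cov, 1), np.nan)
    for i in range(len(cells)):
        covered = cov[i] > 0
        f = frac[i, covered]
        if f.size < 2:
            continue
        w = cov[i, covered] if coverage_weighted else np.ones(f.size)
        wmean = np.average(f, weights=w)
        wvar = np.average((f - wmean) ** 2, weights=w)
        if wvar <= 0:
            continue
        est = wmean * (1 - wmean) / wvar - 1
        if est > 0:
            nu[i] = est

    alpha = (mu * nu)[:, None]
    beta = ((1 - mu) * nu)[:, None]
    levels = (mc + alpha) / (cov + alpha + beta)
    return PosteriorLevels(
        cells=cells,
        feature_ids=counts.features.ids,
        levels=levels,
        prior_mean=mu,
        prior_strength=nu,
    )


def normalize_rna(
    umi: np.ndarray,
    cells: np.ndarray | None = None,
    genes: np.ndarray | None = None,
) -> NormalizedExpression:
    """Library-size normalize UMI counts and log transform.

    value = ln(1 + count / cell_total * mean_total), mean_total taken over all
    cells in the matrix.  Cells with zero total are excluded.
    """
    umi = np.asarray(umi, dtype=float)
    if (umi < 0).any():
        raise ValueError("counts must be non-negative")
    n, g = umi.shape
    if cells is None:
        cells = np.array([f"cell{i}" for i in range(n)])
    if genes is None:
        genes = np.array([f"gene{j}" for j in range(g)])
    totals = umi.sum(axis=1)
    ok = totals > 0
    if not ok.all():
        logger.warning("excluding %d cells with zero UMI total", (~ok).sum())
    umi, totals = umi[ok], totals[ok]
    mean_total = totals.mean()
    values = np.log1p(umi / totals[:, None] * mean_total)
    return NormalizedExpression(cells=np.asarray(cells)[ok], genes=np.asarray(genes), values=values)


def filter_features_by_coverage(
    counts: MethylCountMatrix, min_mean_basecalls: float = 500.0
) -> FeatureSet:
    """Keep features whose mean total basecalls across cells is >= the cutoff."""
    mean_cov = counts.cov.mean(axis=0)
    keep = mean_cov >= min_mean_basecalls
    return FeatureSet(counts.features.table.loc[keep].reset_index(drop=True))


def select_integration_features(
    mc_levels: pd.DataFrame,
    expr: pd.DataFrame,
    cegs: list[str] | np.ndarray,
    mch_var_min: float = 0.05,
    expr_var_min: float = 0.005,
) -> np.ndarray:
    """Select cluster-enriched genes variable in both modalities.

    ``mc_levels`` and ``expr`` are cell-by-gene frames (possibly from different
    cells); a CEG is retained when its mCH variance across methylation cells
    exceeds ``mch_var_min`` and its expression variance exceeds ``expr_var_min``.
    Downstream integration uses the *negated* mCH values because gene-body mCH
    is anticorrelated with expression; negation is the caller's concern.
    """
    cegs = np.asarray(cegs)
    shared = [g for g in cegs if g in mc_levels.columns and g in expr.columns]
    if len(shared) < len(cegs):
        raise ValueError("cegs must be a subset of the shared genes of both matrices")
    mch_var = mc_levels[shared].var(axis=0, ddof=0)
    expr_var = expr[shared].var(axis=0, ddof=0)
    keep = np.array(shared)[(mch_var > mch_var_min).values & (expr_var > expr_var_min).values]
    if keep.size == 0:
        raise ValueError(
            "no integration features pass the variance thresholds "
            f"(mCH>{mch_var_min}, expr>{expr_var_min}); inspect input variances"
        )
    return keep


def reduce_dimensions(
    matrix: np.ndarray,
    n_components: int,
    mode: str = "fit",
    model: EmbeddingSpace | None = None,
) -> EmbeddingSpace | np.ndarray:
    """Centred SVD reduction with singular-value-normalized components.

    ``fit`` mode fits on ``matrix`` and returns an :class:`EmbeddingSpace`
    whose coordinates are U (each retained component has unit L2 norm over the
    fitting cells, because the projection is divided by the singular value).
    ``transform`` mode applies a fitted model to new rows.
    """
    if mode == "transform":
        if model is None:
            raise ValueError("transform mode requires a fitted model")
        return model.transform(matrix)
    if mode != "fit":
        raise ValueError(f"unknown mode {mode!r}")
    X = np.asarray(matrix, dtype=float)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating to {k}"
        )
    return EmbeddingSpace(
        coords=U[:, :k],
        singular_values=s[:k],
        loadings=Vt[:k].T,
        mean_=mean,
    )
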