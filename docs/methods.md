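# Methods

This note documents the models and procedures implemented in `epiretro`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Count model and posterior methylation levels

Single-nucleus methylome data are cell × feature pairs of methylated (`mc`)
and total (`cov`) basecall counts, in CH, CG or CCC cytosine context.
Features are 100-kb bins tiling the genome (half-open, trailing partial bin
retained, matching `bedtools makewindows`) or gene bodies extended 2 kb on
both sides; sex chromosomes are removed before analysis so X-inactivation
does not masquerade as cell-type signal.

Because any one feature is shallowly covered in any one cell, raw fractions
are unstable.  Levels are therefore posterior means under a beta-binomial
model: per cell, a Beta(α, β) prior with mean μ = Σmc/Σcov over its features
and strength ν estimated by method of moments on the per-feature raw
fractions — for a Beta with mean μ, var = μ(1−μ)/(ν+1), so
ν = μ(1−μ)/v̂ − 1.  The moment variance is coverage-weighted by default; an
unweighted switch exists (`coverage_weighted=False`) because either
convention is defensible and the difference is small at realistic coverage.
When the estimate degenerates (v̂ ≤ 0 or ν ≤ 0) the strength falls back to
ν = 1, a weakly informative prior.  Zero-coverage entries equal the cell's
prior mean; cells with zero total coverage are excluded.  Shrinkage is
monotone in coverage, which the test suite asserts directly.

RNA counts are library-size normalized as ln(1 + count/total × mean_total)
(natural log, pseudocount 1 — unstated conventions chosen once, both
monotone, so rank-based statistics are unaffected).

## Quality control

The QC ladder runs in order: (1) cell filters — experiment median mCCC
< 0.025, 500,000 < nonclonal reads < 10,000,000, cell mCCC < 0.05, all
bounds strict (mCCC proxies bisulfite non-conversion); (2) doublet removal
(below); (3) experiments with fewer than 20 neurons dropped; (4) the
contamination gate.  For each FANS run, observed on-/off-target neuron counts
are compared with expected counts from unbiased reference data:
FE = (O_on·E_off)/(O_off·E_on), p = Pr(X ≥ O_on) for
X ~ Binomial(O_on+O_off, E_on/(E_on+E_off)).  A run passes at FE ≥ threshold
(8 for extratelencephalic targets, 3 for intratelencephalic) and BH-adjusted
p < 0.001.  The BH family is the set of runs sharing a target class
(switchable to a single global family; the grouping is a judgment call the
original description leaves implicit).  On-/off-target subclass definitions
are configuration, not code.  Expected counts are inputs: estimating them
from dissection-imbalanced unbiased data is out of scope.

## Label transfer, doublets, hierarchy

Transfer weights follow the exact chain d′ = 1 − d/max(d),
d″ = 1 − e^(−d′/2), w = d″/Σd″ over the k nearest labelled neighbours
(Euclidean, k = 25 for cluster/subclass transfer, 5 for sparse-data
transfers; both exposed).  The transform is scale invariant and assigns the
farthest neighbour weight zero.  When all distances are equal the transform
is 0/0; the uniform 1/k fallback is its limit of intent and triggers a
warning.  Categorical labels transfer as one-hot averages (rows sum to 1
exactly); continuous values (e.g. embedding coordinates) as weighted means.
Argmax ties break by category order.

Doublet removal classifies query cells against a reference carrying
predicted-doublet exemplars, twice: round 1 against all level-1 clusters plus
the doublet class using a reduction fit on the whole reference; round 2
within each assigned cluster with all reference doublets re-injected and the
reduction refit per cluster (the per-cluster refit is one reading of the
original workflow; it is the one implemented).  Hierarchical classification
then walks nested label levels, restricting candidates at each level to the
children of the previous assignment; branches without deeper labels stop at
their deepest level.

Classification uses *unnormalized* principal projections (coordinates
multiplied back by the singular values).  This matters: the
singular-value-normalized embedding used for integration equalizes component
scales, which is right for co-embedding but amplifies noise components
relative to signal in kNN voting and destabilizes doublet detection.  The
benchmark conditions for doublet flagging include a reference with roughly
ten doublet exemplars per cluster pair — the method genuinely requires
exemplar density, which the study's 300k-cell unbiased atlas supplies in
practice.

## Integration

CCA between z-scored cell × gene matrices X (methylation, negated mCH) and Y
(expression) is solved by SVD of X Yᵀ.  Fitting scales with cell count, so a
seeded reference subsample fits the model and all other cells extend exactly:
U_qry = X_qry(Y_refᵀV_ref)/S, V_qry = Y_qry(X_refᵀU_ref)/S.  Extension of the
reference reproduces the fit, asserted at 1e-8 in CI.  Canonical vectors are
row-L2-normalized before neighbour search.  Integration features are
cluster-enriched genes (CEGs) with mCH variance > 0.05 and expression
variance > 0.005; the CEG definition itself (per-cluster one-vs-rest
rank-sum markers) is a reproducible stand-in, configurable.  For
methylation–methylation pairs a reciprocal-reduction mode searches neighbours
in each dataset's own reduction.

Anchors are mutual 5-nearest-neighbour pairs, scored by the shared-neighbour
count of the paired cells' neighbourhoods (size 30) in the combined set,
rescaled linearly between the 1st and 90th percentiles and clipped to [0, 1]
(Seurat-v3 conventions; none of these constants is load-bearing and all are
arguments).  Alignment subtracts from each query cell a weighted average of
anchor difference vectors, weights from the same d→w transform over its 100
nearest anchors multiplied by anchor scores (multiplicative use of scores is
the default; a filtering mode would be the alternative reading).  Reference
coordinates are returned untouched.  Joint clustering is Leiden
(RBConfiguration) on the Euclidean kNN graph, k = 25, resolution 1.0, seeded,
labels ordered by cluster size.  At a few hundred cells that resolution
over-partitions — the tests assert refinement of planted structure at the
default and exact recovery at blob-scale resolution.

## Discriminability

For two projection targets from one source, an L2 logistic regression
(C = 1, deterministic solver, no feature standardization — posterior levels
are already bounded) predicts the target from gene-body posterior mCH,
restricted to features with ≥ 500 mean basecalls on real data (the benchmark
cohorts use a threshold scaled to their simulated coverage; the filter's role
is identical).  Computational replicates: 50 seeded stratified half/half
splits, mean held-out AUROC.  Biological replicates: train on one sex, test
on the other, both directions averaged; pairs with one sex are reported
unavailable.  Both classes need ≥ 10 cells.  Cross-source transfer fits on
one source and evaluates on another; the diagonal equals the within-source
result.  Gene categories are compared at matched sizes (larger categories
downsampled, seeded, five draws) with two-sided Wilcoxon signed-rank across
comparisons and BH across category pairs.

Differentially methylated genes between classes use per-source two-sided
rank-sum tests with BH, requiring FDR < 0.01 and mean-mCH ratio > 1.25×
(thresholds unstated in the source description; these defaults are reported
in provenance and configurable); the union over sources is emitted with a
source × gene log2 fold-change matrix.

## Projection enrichment

Per target within a source: the proportion of its neurons in each joint
cluster (summing to 1 over clusters), association at proportion > 5%, and a
one-sided Fisher exact test of this target versus all others in/out of the
cluster, BH over (cluster, target) pairs, FDR < 0.01.  Displayed values are
proportions z-scored within cluster across targets (defined as 0 when fewer
than two targets or zero variance, flagged).  Absolute proportions are used
rather than ratios to unbiased data because unbiased profiling sequenced
dissections to equal depth, inflating small dissections; a relative mode
exists but is off by default.  Sex differences: two-sided Fisher per cluster,
BH across clusters, only when both sexes are present.  Mixed-effects
replicate modelling is deliberately out of scope.  Neurotransmitter summaries
report mean normalized expression per cluster for a marker panel and per-cell
reciprocal mCH (1/level, floored at 1e-3 to avoid division by zero).

## Regulatory layers

DEGs: per cluster pair, two-sided rank-sum per gene on normalized expression,
BH across genes; fold change is the ratio of mean linear-scale normalized
expression with pseudocount 0.01 (ratio semantics require the linear scale);
|log2FC| > 1 and FDR < 0.01; at most the top 100 per pair by FDR then |FC|;
union across pairs.  Pseudobulk methylation is the pooled fraction Σmc/Σcov
per cluster, clusters under 30 cells excluded.

Hypo-DMRs: flag(d, c) iff mCG(d, c) is strictly below the 10th quantile of
all values in the region group AND below the 10th quantile of DMR d across
clusters (linear-interpolation quantiles; NaNs ignored).  The flag count is
non-decreasing in q.

Motif enrichment follows the recovery-curve statistic: DMRs ranked by motif
score (descending, ties by DMR id), recovery = fraction of the cluster's
hypo-set seen by each rank, AUC = mean recovery over the top
ceil(0.05 × N) ranks (the top fraction mirrors the cisTarget default and is
an argument), NES = z-score of the AUC against the whole motif collection;
enriched at AUC > 0.01 and NES > 3.  The scanner is a deliberate
simplification: a log-odds PWM maximum over positions and strands against a
uniform 0.25 background, with a hit threshold at 80% of the motif's maximum
attainable score, instead of an HMM over motif clusters.  The enrichment
statistic — the contribution — is implemented faithfully; the scanner is the
substrate it runs on.  Enriched TFs must additionally be expressed (> 0) and
not silenced (normalized mCH < 1) in at least one enriched cluster.

DMR–gene association: candidate pairs within 1 Mb of the TSS (DMR midpoint);
Pearson correlation across cluster pseudobulk profiles; the null permutes
feature values independently within each cluster, 100 shuffles (seeded);
empirical FDR at threshold t is (mean null exceedances)/(observed
exceedances), and edges at the loosest t controlling FDR < 0.01 are kept.
The default retains positive correlations (mCG and gene-body mCH rising
together under co-repression); a two-sided mode exists because the original
account is ambiguous about the sign convention, and GRN edges use the
two-sided gate.  GRN triplets require all three shuffle-FDR-significant edges
(TF–DMR with a motif hit, TF–target, DMR–target within the window) on
matrices quantile-normalized within each cluster across features (expression
matrices jointly, mCG separately).  Correlation-based networks capture
indirect and false-positive links; no causal claim is made.

## Spatial smoothing

For in-situ cell i: its k_spatial = 25 nearest same-slice neighbours
(distances Ds, never crossing slices) and each neighbour's k_ref = 25 nearest
reference cells in the integrated embedding (distances Dr).  Both pass
through the unnormalized second-stage transform d″ = 1 − e^(−d′/2); the
combined weight of the k'-th reference neighbour of the j-th spatial
neighbour is the product Ds″(i, j)·Dr″(Ns(i, j), k'), normalized once over
the full row (literal reading of the product formula), giving up to 625
weighted votes per cell.  Second-stage reference distances are cached from
the global integration rather than recomputed per spatial neighbour.  Slices
with fewer than k_spatial cells use all available neighbours with a warning.
Occupancy mapping reports per-slice cluster counts, centroids and bounding
boxes.

## The synthetic generator

`simulate_multiomic_cohort` emulates the statistical skeleton of the real
data: per-feature coverage Poisson(coverage_mean), methylated counts
Binomial(cov, rate); per-gene baseline mCH rates lognormal around a global
mean of 0.04 (typical neuronal gene-body mCH); cluster markers at
marker_effect × baseline in their own cluster; RNA negative-binomial
(gamma–Poisson, shape 10) with mean = base × global_mch_mean/rate, the
simplest monotone inverse link, so marker mCH and expression are
anticorrelated by construction; doublets as unweighted 50/50 rate mixtures
(the hardest-to-detect midpoint); projection labels per cluster with a
uniform contamination fraction; sexes alternating so biological splits always
exist.  Spatial slices place each region in its own block with a gap wider
than the neighbourhood radius, and flip exactly round(noise_rate × n) labels.
Planted motif sites are sampled from the PWM conditioned on passing the
scanner threshold — a planted *functional* site must be recognizable by
the declared scanner, otherwise the fixture would encode scanner misses as
ground truth.  All randomness flows from one seeded generator; identical
configs give byte-identical outputs.

What the generator does not emulate: chromatin-level correlation structure
along the genome, bisulfite conversion errors, batch and replicate effects,
ambient contamination gradients, or realistic cluster-size imbalance.
Passing the planted-truth benchmarks therefore demonstrates that the
implementations are correct and well-calibrated under their stated
assumptions — not that the pipeline's thresholds are optimal for any
particular real dataset.

## Benchmark problem sizes

The standard evaluation conditions (in `epiretro.benchmarks`) are sized for a
single CPU: cohorts of 300–500 cells and 200–300 genes, 30-cluster pseudobulk
profiles, 2,200 DMR–gene candidates with 100 shuffles, 50-motif collections
over 300 sequences, 10,000 simulated FANS runs, and 20 spatial replicates of
200 cells.  These sizes were chosen once as the smallest at which each
statistic's behaviour is unambiguous (signal recovery saturates and null
rates resolve below their thresholds).

## Known limitations

- The CEG stand-in and the DMG/DEG thresholds are reproducible defaults, not
  recovered constants; analyses of real data should treat them as starting
  points.
- The PWM scanner ignores motif-cluster structure and higher-order sequence
  composition; motifs with strong strand or flanking preferences will score
  differently than under an HMM scanner.
- Doublet flagging depends on doublet-exemplar density in the reference (see
  above); with sparse exemplars sensitivity degrades gracefully but
  substantially.
- Leiden resolution 1.0 is calibrated for atlas-scale graphs; small datasets
  need smaller resolutions, as the tests make explicit.
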