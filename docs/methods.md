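# Methods

This note documents the models and procedures implemented in `scqc`, the
choices made where the design was genuinely open, and what the synthetic
data used in the test suite does and does not establish about real data.

## The data model

All computation runs over `SCEDataset`: a features x cells container with
named assays (tagged `counts`, `tpm`, `cpm`, `fpkm`, `normalized`,
`log_expression` or `residuals`), cell- and feature-metadata tables,
named control-feature sets, named per-cell size-factor vectors, named
cells x k reduced-dimension matrices, and opaque `extra_slots` for
objects the package stores but never computes on (bootstrap
quantification replicates, cell-cell/gene-gene distance matrices,
consensus clusterings). The feature-major orientation is fixed
everywhere; a single convention prevents silent transposition bugs.
Subsetting restricts every slot together and preserves the dataset's id
order; combining datasets concatenates cells over identical feature sets,
unions metadata columns with explicit missing markers (NA, never zero),
and drops stored embeddings because embeddings of separate runs are not
concatenable. Sparse (scipy) and dense (numpy) assays sit behind one
contract; a densify guard refuses to expand a sparse matrix beyond a
configurable element count (default 5e7).

Metadata columns that share a name but carry incompatible dtypes make
`combine_cells` fail rather than coerce; silent type coercion is how
factor levels turn into strings of integers. Size-factor entries present
in only one operand are dropped with a warning, since a factor computed
on half the cells is not meaningful for the union.

## QC metrics

Per cell: total counts; log10(total+1); number of features with value
strictly greater than the detection threshold (default 0 — the data
decide what "expressed" means, and a strict inequality makes zero counts
unambiguous); percentage of counts in the top-k expressed features for
k in {50, 100, 200, 500} (clipped to the feature count; the cumulative
top-k sum is invariant to how ties are ordered); and, per control set S,
`pct_counts_S`, `n_detected_S` and `log10_counts_S`, plus the endogenous
(no-control) totals. Per feature: mean expression, total counts, number
and percentage of expressing cells, share of the grand total, and
dropout percentage. All log-scaled count metrics use log10(x+1). Cells
with zero totals get all percentage metrics defined as 0, with a logged
warning. Recomputation drops and rewrites the QC columns, so the
operation is idempotent.

## Outlier detection

Low-quality cells are flagged with the two-phase principal-component
scheme of Filzmoser, Maronna & Werner (2008) applied to QC metrics.
Default variables (when control sets exist): `pct_counts_top_100`,
`total_features`, `pct_counts_S`, `n_detected_S`,
`log10_counts_endogenous`, `log10_counts_S`. Both "log-scaled" and
"log-transformed" count variables use the same log10(x+1) transform.

1. Each variable is sphered by (x - median)/MAD (MAD scaled by 1.4826
   for normal consistency). Variables with MAD = 0 are dropped with a
   warning rather than dividing by zero.
2. Principal components of the sphered data covering >= 99% of variance
   are retained and re-sphered by their own median/MAD.
3. Phase 1 (location outliers): components are weighted by absolute
   excess kurtosis |mean(z^4) - 3| (normalized to sum 1); the weighted
   norm d1 = sqrt(sum_j w_j z_j^2) is scaled so its median matches the
   chi distribution's, then mapped to w1 by a translated biweight that is
   1 below the 1/3 distance quantile and 0 above median + 2.5 MAD.
4. Phase 2 (scatter outliers): the unweighted norm is mapped to w2 with
   cutoffs at the chi-square 0.25 and 0.99 quantiles for the retained
   dimension.
5. Final weight w = (w1 + s)(w2 + s)/(1 + s)^2 with s = 0.25; cells with
   w < 0.25 are flagged. Every constant is exposed in `PcoutConfig`.

The kurtosis weights enter the squared distance linearly
(Mahalanobis-style, as in the method's defining formula), not through a
component-rescaling matrix. The procedure contains no randomness.

**Known property: over-flagging.** The translated-biweight constants
adapt to the scale of the empirical distance distribution but not to its
shape, and under homogeneous data the kurtosis weights concentrate on
arbitrary components, stretching the phase-1 distance tail relative to
its chi-square calibration. Measured on exact multivariate-normal data
(n = 100, p = 5) the default constants flag roughly 5–10% of
unremarkable cells; the original publication's own simulations report
false-positive rates of the same order. Planted strong outliers are
recovered essentially perfectly (they take the lowest final weights),
but flagged cells near the cutoff should be reviewed on the QC PCA plot
rather than discarded automatically. Raising `scatter_c_quantile` /
`location_c` trades sensitivity for specificity.

## Explanatory variance

For each gene and each metadata variable, a one-covariate least-squares
fit (categorical variables one-hot encoded against the alphabetically
first level; continuous variables as-is) gives R^2 = 1 - RSS/TSS,
clipped to [0, 1]; zero-variance genes get R^2 = 0 by convention. The
response is the `log_expression` assay by default — linear models on raw
counts are dominated by sequencing depth. Cells with missing values are
dropped per variable; single-level variables are dropped with a warning.
Variables are ranked by median R^2 descending with alphabetical
tie-breaks. The analysis is descriptive, so no multiple-testing
machinery is attached. `pcs_vs_variable` applies the same R^2 to
principal-component scores as responses, which is how a batch factor
aligned with PC1 is diagnosed.

## Normalization and batch correction

Size-factor methods (all scale-equivariant, all optionally rescaled to
geometric mean 1):

* **library** — column sum over mean column sum.
* **RLE** — per cell, median over features of count / geometric-mean
  reference; features with any zero across cells are excluded from the
  reference (an empty reference is an error advising feature filtering).
* **TMM** — the reference cell is the one whose upper quartile of
  positive counts is closest to the mean upper quartile. Per cell,
  M = log2 count ratio and A = average log2 abundance against the
  reference; genes outside the central 1-2*0.30 span of M or 1-2*0.05
  span of A are trimmed, and the factor is 2 to the precision-weighted
  mean of the kept M-values with inverse binomial-variance weights
  (N - y)/(N y) summed over the pair. Trimming uses order-statistic
  value bounds with boundary ties kept, making the mask independent of
  tie order; when all M-values are equal the untrimmed weighted mean is
  used, so an exactly scaled cell pair recovers the scale constant
  exactly. M/A are computed on raw count ratios so the result acts
  directly as a size factor (a depth-prenormalized convention would
  return 1 for a uniformly scaled pair).
* **UQ** — 75th percentile (type-7 linear interpolation, stated because
  quantile dialects differ) of each cell's counts over features nonzero
  in at least one cell, divided by the mean percentile.

Cells with all-zero counts are an error naming the cell. Normalized
expression is count/factor; log expression is log2(normalized +
pseudocount), pseudocount 1 so zeros map to zero.

`regress_out` fits each gene on a full-rank design matrix (intercept
plus reference-level one-hot / numeric columns; aliased columns dropped
with a log message at build time, rank deficiency at fit time is an
error) and returns residuals plus the fitted intercept, preserving each
gene's location while removing nuisance terms. The operation is
deterministic and idempotent. Least-squares residuals assume roughly
symmetric noise; genes with more than 50% zeros trigger a logged warning
because their residuals can be poorly behaved.

## Embeddings

Feature selection takes the top-n (default 500) features by variance of
the chosen assay (log scale recommended; raw-scale variance selects only
high-abundance genes), ties broken by feature id; a user-supplied gene
set (e.g. cell-cycle genes) bypasses selection. PCA centres and, by
default, scales features to unit variance (the switch is exposed; scaling
stops high-variance genes from dominating), then takes an exact SVD with
a deterministic sign convention (largest-magnitude loading positive);
variance fractions are shares of the total variance of the centred,
scaled matrix. MDS is classical Torgerson double-centring with negative
eigenvalues clipped at zero. t-SNE wraps scikit-learn with a mandatory
recorded seed and PCA initialisation; default perplexity 30, always
logged. The diffusion map builds a Gaussian kernel on Euclidean
distances (width: median pairwise distance unless given, recorded in the
embedding), symmetrically normalises the transition operator, and uses
the first k non-trivial eigenvectors scaled by their eigenvalues. Every
embedding is stored into `reduced_dims` under its method name and is
retrievable by the generic accessor alongside externally computed
representations.

## Plot statistics

Each diagnostic plot has a pure, numerically tested computation:
cumulative top-k expression profiles (k = 1..K, default K = 500, all k
computed), the n highest-total features with overall and per-cell count
shares, and frequency-of-expression vs mean expression with reference
lines at the median feature mean and 50% frequency. Cumulative curves
are the default view of expression distributions; boxplots handle the
mass of zero/low observations poorly. `render` is the only file-writing
operation; categorical axes are jittered with a seeded jitter (default
seed 0) and SVG/PDF output strips timestamps and fixes the hash salt so
identical inputs give byte-identical vector files.

## Quantification import

kallisto `abundance.tsv` and Salmon `quant.sf` tables are parsed by
column name (so reordered headers are fine), validated to share one
transcript universe, and collapsed to gene level through a many-to-one
transcript-to-gene TSV by summing counts and TPM per gene; mass is
conserved exactly over mapped transcripts, and summing TPM (rather than
recomputing it from collapsed counts and lengths) is the documented
choice. Per-cell TPM columns are sanity-checked against a 1e6 total with
0.1 slack for upstream rounding. Bootstrap files are recorded as opaque
paths, never parsed. Running the quantifiers themselves is out of scope.

## Synthetic data

The generator draws gene means log-normal(1, 1.5) — a long-tailed
abundance distribution with median ~e, typical of moderately sequenced
single-cell libraries; spike-in means log-normal(3, 0.5), giving a
20-species pool that contributes roughly 5% of a healthy cell's counts;
per-cell depth factors log-normal(0, 0.3), a 2-3x depth range; and
counts gamma-Poisson with dispersion 0.1, the standard overdispersed
scRNA-seq model, so dropout arises from low means without a separate
zero-inflation knob. Planted structure: low-quality cells multiply
endogenous (not spike-in) means by a capture efficiency in (0, 1], so
their spike-in share rises and detected features fall; a batch doubles
as 2^lfc on a fixed fraction of genes in the second half of cells; a
"machine" factor is assigned independently of expression as a built-in
null variable. The generator is fully seeded and reproducible.

What the simulations do not emulate: gene-gene correlation (cell types,
pathways, cell cycle), ambient RNA, doublets, UMI saturation, or
batch effects that change variance rather than means. Passing the
planted-recovery tests therefore shows the estimators recover the
signals they model, not that real datasets are this clean; on real data
the outlier detector in particular should be treated as a screen.

Problem sizes in the test suite and acceptance script (1000 genes x 100
cells for the recovery checks, 20-gene instances for the TMM oracle,
5 random 10 x 20 matrices for the PCA oracle) are chosen so the whole
suite completes in seconds while leaving Monte-Carlo margins far wider
than the assertion tolerances.

## Numerical choices and degenerate inputs

* Quantiles: numpy's default linear interpolation (type 7) throughout.
* MAD uses the 1.4826 normal-consistency constant.
* Exact oracles assert at 1e-8..1e-12; conservation laws at
  summation-order rounding (1e-12 relative).
* Degenerate guards: empty subset results, all-zero cells in size
  factors, constant matrices in feature selection, identical cells in
  diffusion maps, rank-deficient designs and single-level variables all
  raise typed `DatasetError`s with corrective hints; zero-total cells in
  QC and cumulative profiles warn and return defined zeros.

## Command line

The `scqc` tool wires the modules into a workflow
(`simulate`, `import`, `qc`, `outliers`, `explain`, `normalize`,
`dimred`, `plot`) over an on-disk dataset directory (MatrixMarket or
dense TSV assays plus TSV/JSON metadata, floats at 17 significant digits
so write/read round-trips float64 exactly). JSON configs with CLI-flag
overrides (flags win), logs to stderr, data only to files, and a
`run_manifest.json` per run recording versions, seed, parameters and
SHA-256 input hashes. Exit codes: 0 ok, 2 usage, 3 data error.
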