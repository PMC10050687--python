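# Methods

This note documents the models and procedures implemented in
`marrowatlas`, the assumptions behind them, the tunable parameters, and
the design choices made where the design was genuinely open.

## Data model

A `CellDataset` is a sparse genes × cells matrix of nonnegative integer
UMI counts plus three aligned tables (cells, genes, samples).  On disk
it is Matrix Market plus TSVs, which keeps every artefact plain text and
diffable.  Mitochondrial and ribosomal genes are identified by an
explicit boolean column when present, otherwise by symbol prefix
(`MT-`, `RPL`/`RPS`); real annotations vary, so the override column is
the authoritative path.

## Quality control and normalisation

Cells are filtered on UMI count, detected genes, and mitochondrial /
ribosomal fractions; afterwards whole samples retaining fewer than
`min_cells_per_sample` cells (default 200) are removed.  Public
datasets come from heterogeneous experiments and no universal numeric
cut-offs exist, so thresholds are explicit configuration with documented
defaults (`min_genes` 200, `max_mito_fraction` 0.2), and a per-sample
adaptive rule (median ± k·MAD of log-scale metrics, k = 3) is available.
Each removed cell is attributed exactly one removal reason (first
failing bound in a fixed order), so reasons partition the removed set
and the filter is idempotent.

Normalisation is total-count scaling to `scale_factor` (default 10,000)
followed by log1p:
`normalized[g,c] = log(1 + counts[g,c] / total[c] · scale_factor)`.
Zero-total cells are a QC failure, not a normalisation case.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
at desk scale.  Counts are negative binomial (gamma–Poisson) with fixed
dispersion 0.3 (Poisson optional); the per-cell mean profile is

    μ = softplus-free exp( base + marker boost + age slope · (age − 43)
                           + study batch factor + cell size factor )

rescaled to an expected library size (`sequencing_depth`, default 2,000
UMIs).  Defaults fix the study conditions: 3 studies, donor ages uniform
on 2–84 years, four cell types with base proportions .35/.30/.20/.15 and
logit-scale proportion slopes −0.01/+0.01/0/0 per year (one
naive-lymphoid-like shrinking population, one effector/memory-like
growing one, two null), 20 disjoint marker genes per type boosted by
+2 natural-log units, 20 age genes per type with log-slope 0.01/year and
alternating sign, and per-study gene-wise log-normal batch factors with
SD 0.15.  Expected compositions follow the logit-linear trend clipped to
(0.001, 0.999) and renormalised; realised compositions are multinomial.

Query cohorts reuse the reference's structural parameters with a fresh
batch factor.  Abnormal cells are planted by displacing the log-mean of
50 genes (drawn from the above-median-expression pool — an aberrant
programme involves expressed genes) by ± `shift_magnitude` natural-log
units each along a fixed sign pattern shared by all abnormal cells,
mimicking one aberrant programme rather than global scaling.

What the generator does **not** emulate: gene–gene correlation networks,
doublets, ambient RNA, sample-specific depth gradients, or realistic
cell-type hierarchies.  Passing tests therefore demonstrate that each
stage recovers the structure it models, not that it is robust to every
real-data pathology.

## Reference embedding

Per sample, genes are ranked by the variance of their log-normalised
expression (the log transform is the variance stabiliser), ties broken
by higher mean then gene id; the top `per_sample_n` (default 3,000) per
sample are merged, and genes are re-ranked by the number of samples
whose top lists contain them (ties: higher mean variance, then gene id),
keeping the top `consensus_n` (default 3,000).  This consensus rule
prevents a single deeply sequenced sample from dominating feature
selection.

Selected genes are standardised to zero mean / unit variance with
values clipped at ±10 (guarding PCA against outlier cells) and the
first 30 principal components are taken via randomised SVD with a fixed
seed and a deterministic sign convention (largest-magnitude loading
entry positive), making the embedding byte-reproducible.  The scaling
statistics and loadings are frozen: query data is projected with the
*reference* means, SDs and loadings, genes absent from a query imputed
as zero expression before scaling.  A query must share at least 50 % of
the feature genes.

Batch correction operates in PC space: studies are merged in decreasing
size order; mutual nearest neighbour pairs (k = 20) between the growing
corrected pool and each incoming study define correction vectors that
are Gaussian-kernel smoothed over the incoming cells (bandwidth =
median distance to the nearest paired cell).  Like all MNN-style
corrections this assumes the batch offset is small relative to
between-population distances, or (equivalently) approximately orthogonal
to the biological subspace; under that assumption a constant offset is
removed almost exactly, and a single study passes through unchanged.
The correction is pluggable — any `(embedding, studies) → embedding`
function can replace it.

Clustering builds an unweighted, undirected kNN graph (Euclidean,
k = 20) and runs Louvain modularity optimisation with a seeded RNG.
On sparse kNN graphs modularity will split a single homogeneous
population into sub-communities when k is small relative to the
population size; k should grow with expected cluster sizes (the blob
recovery test uses k = 30 for 200-cell clusters).  Cluster markers are
one-vs-rest Wilcoxon rank-sum tests per gene with natural-log fold
changes of de-logged means (pseudocount 1) and BH adjustment; clusters
under 3 cells are skipped.

## Composition trends

Per-sample cell-type proportions (fractions, rows summing to 1 — the
percentage scale is a ×100 rescaling of β) are regressed on age with an
intercept and categorical study dummies (reference level = first study
alphabetically); the model as printed lacks an intercept and treats the
project term loosely, and this is the standard identifiable reading.
The combined evidence is the two-sided t-test on the age coefficient;
an F-test alternative was considered and rejected because the age
coefficient is the quantity of interest.  Per-study Spearman ρ/p are
reported for studies with ≥ 3 samples, with optional Fisher combination.
A constant response returns β = 0, p = 1 rather than a 0/0 failure, and
identical ages raise a degenerate-design error.

## Age genes and enrichment

Pseudobulk is the mean expression of each cell type in each sample.
Eligibility follows the screening rules: a type must appear with ≥ 20
cells in ≥ 20 samples (the per-sample reading; a pooled-total mode is a
switch), and within a type only genes detected in > 10 % (strict) of its
cells are kept, evaluated per cell type.  Because this pipeline's batch
correction lives in PC space, gene-level corrected expression does not
exist; study effects are instead removed at the pseudobulk level per
cell type by least squares with sum-coded study dummies and age
protected (the removeBatchEffect construction).  Pearson correlation
with age is tested against the t-distribution with n − 2 df (adequate at
these sample sizes; a permutation mode would be the alternative for very
small n), retaining genes at p < 0.01.  Over-representation of a hit
list in GMT gene sets uses the hypergeometric upper tail with BH
adjustment across sets; gene sets are user-supplied since hosted
databases are unpinned.

## Age clock

One elastic net per eligible cell type, features restricted to that
type's age genes, fitted on internally standardised features.  The
penalty path is 100 log-spaced λ values spanning four decades below
λ_max = max|Zᵀ(y − ȳ)| / (n·α) with mixing α = 0.5 by default; λ is
chosen by 10-fold cross-validated MSE (minimum rule; the 1-SE rule is an
option).  λ = 0 falls back to OLS, λ → ∞ yields the mean-age intercept.
The solver tolerance is 1e-8 so fitted solutions satisfy the elastic-net
KKT conditions to ~1e-4.  A sample's predicted age is the median of its
per-cell-type predictions (even counts: mean of the central two);
negative predictions are flagged, never clipped.  Evaluation uses
sample-level folds — every cell type of a sample sits in the same fold —
so no sample informs its own prediction; gene *selection* is taken as
given (matching the screening-then-training procedure), which the
shuffle test shows contributes no leakage pathway on its own.
When a mapping gate is available, pseudobulk for prediction should be
recomputed from confidently mapped cells only (filter the dataset by
`MappingResult.confident_cells()` before `pseudobulk`, with
`min_samples=0` since prediction needs no cohort-level eligibility).

## Query mapping and the confidence gate

Query cells are projected with the frozen transform and labelled by the
modal cell type of their 30 nearest reference neighbours (ties: larger
summed inverse distance, then lexicographic).  The confidence score is
the inverse of the **mean** distance to those neighbours (the median is
a switch), plus ε = 1e-12 against exact duplicates, min-max normalised
over the query dataset.  A two-component 1-D Gaussian mixture is fitted
to the scores by EM (k-means initialisation with a fixed seed,
convergence at ΔlogL < 1e-8 or 500 iterations, variance floor 1e-6
against point masses); cells with posterior ≥ 0.5 for the *higher-mean*
component are confident — low scores mean the cell sits far from
anything in the healthy reference.  Degenerate inputs (all scores equal)
yield a flagged gate with every cell confident.  Frozen-transform
projection was chosen over symmetric re-integration to keep the
reference immutable and the mapping deterministic.

Disease-vs-healthy DE compares query cells of a type against the
reference's cells of the same type by Wilcoxon rank-sum, with
logFC = ln((mean expm1 + 1)query / (mean expm1 + 1)ref) and significance
at p < 0.05 and |logFC| > 0.5.  Note a compositional caveat: an extreme
aberrant programme captures a large share of each cell's library, so
*every* gene's relative abundance shifts under total-count
normalisation; direction-aware recovery of the planted programme is the
meaningful check, and the tests use it.

## Numerical and determinism choices

All randomness flows through explicit seeds (NumPy `SeedSequence`
derivation in the generator, seeded randomised SVD, seeded k-means and
CV folds, a seeded igraph RNG for Louvain); every stage rerun with the
same config and seed is byte-identical on disk.  TSV reads use
round-trip float parsing so write→read is exact.  Problem sizes
throughout the tests and the acceptance script — cohorts of 40–60
samples, 100–150 cells per sample, 250–300 genes — are the package's
chosen desk scale: large enough for the planted effects to be
statistically recoverable, small enough to iterate on.

## Known limitations

The MNN correction is a deliberate simplification of anchor-based
integration and only removes shifts expressible in PC space; the
pseudobulk study-effect removal assumes additive batch effects on
log-expression; the clock models age linearly in years; and the
confidence gate assumes the score distribution is well described by two
Gaussian components — heavy contamination or multi-modal query
populations would warrant more components or a nonparametric cut.
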