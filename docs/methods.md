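# Methods

## Model

All analysis operates on log2 intensities (fold-change cutoffs in this
field are conventionally quoted on the log2 scale). A contrast is two
disjoint cohorts of arrays, each with at least two replicates.

The measurement model is

    x_{g,i} = θ_{r,g} + ε_i,     ε_i ~ N(0, σ²_i),

where θ_{r,g} is the true log2 level of gene g in cohort r and σ²_i is
an array-specific error variance, shared by all genes on array i. Error
homogeneity across genes plus heterogeneity across arrays is the
central assumption: it reflects that technical quality varies by array
(hybridization, RNA quality) far more than by gene, and it is what
distinguishes this estimator from gene-wise variance estimation.

### Samplewise error variances

For arrays i, j in one cohort, the per-gene differences
d_g = x_{g,i} − x_{g,j} have variance σ²_i + σ²_j across genes,
provided most genes are non-DEGs within a cohort (differences cancel
θ). The variance of the differences is computed across all genes
(sample variance, ddof 1); each pair variance yields the half-estimate
σ²_{ij}/2 for both members, and the n−1 estimates per array are
averaged:

    σ²_i = ½ · 1/(n−1) · Σ_{j≠i} σ²_{ij}.

For n = 2 the decomposition σ²_1 + σ²_2 = σ²_{12} is exact by
construction. Because per-array additive shifts cancel in d_g, the
estimates are *identical* before and after scaling normalization; the
pipeline estimates them on the raw matrix and a regression test asserts
the invariance. An optional robust variant replaces the sample variance
of d_g with a scaled-MAD variance (Gaussian consistency constant
1.4826²) for heavy-tailed contamination; default off, since the plain
variance is the estimator the model defines and contamination by true
DEGs is second-order when the DEG fraction is modest.

### Normalization

Scaling normalization shifts each array additively on the log scale so
its mean equals the global mean of per-array means — equivalently,
scaling raw intensities to the global geometric mean. All genes
participate; no trimming. The operation is idempotent, and per-gene
differences between two arrays change only by the constant difference
of their offsets, which is why the variance estimation above is
unaffected.

### Cohort posteriors and the z-test

Each measurement is assigned the Gaussian N(x_{g,i}, σ²_i) as the PDF
of its true value. Multiplying a cohort's Gaussians for one gene and
renormalizing gives the precision-weighted posterior of the cohort
mean:

    σ²_r = 1 / Σ_i (1/σ²_i),     μ_r = σ²_r · Σ_i x_{g,i}/σ²_i.

This is the standard product-of-Gaussians result (a flat prior on the
mean); a grid-integration oracle in the test suite confirms it to
1e-6. The fold-change posterior is N(μ_t − μ_c, σ²_t + σ²_c) and

    z = (μ_t − μ_c) / √(σ²_t + σ²_c)

is referred two-sided to the standard normal. p-values are clipped into
(0, 1] at the smallest positive double so downstream FDR input
contracts hold. Benjamini–Hochberg adjustment is applied across all
tested genes with no independent filtering. σ²_t + σ²_c does not depend
on the gene, so the |z| ranking coincides exactly with the |μ_t − μ_c|
ranking; when sample quality is even the posterior mean reduces to the
arithmetic mean and the ranking is plain fold-change ranking. Ties in
rankings are broken by feature id for reproducibility.

Degenerate inputs (identical arrays → zero variance) would give
infinite precision; samplewise variances are floored at 1e-12 log2²
units and the replacement is flagged in the results object.

## Baselines

The pooled two-sample *t*-test uses the common sample standard
deviation S_c = √(((n1−1)S1² + (n2−1)S2²)/(n1+n2−2)) and
t = (x̄_t − x̄_c)/(S_c √(1/n1 + 1/n2)) with n1+n2−2 df (the pooled, not
Welch, form — that is the denominator the comparison targets). Genes
with S_c = 0 and zero mean difference are reported as t = 0, p = 1 with
a degeneracy flag. The hybrid method (HM) selects genes with p < p_cut
AND |log2 FC| > fc_cut, both inequalities strict (defaults 0.05 and
1.0); its selection is by construction a subset of the t-test's p
selection. Both baselines run on the same scaling-normalized matrix as
the z-test, so method comparisons see identical input.

## Enrichment

Overrepresentation of a gene set (size K) in a selection (size n) from
a universe of N annotatable genes is the one-sided hypergeometric upper
tail P(X ≥ k). A function is "detected" at p < 0.001 (strict); no
multiplicity correction is applied to function p-values — the detection
threshold is a fixed significance level, not an FDR. The universe is
the intersection of measured features with the annotation universe,
since enrichment must condition on what was measurable. The chance
benchmark re-draws every set's members uniformly from the universe,
preserving set sizes ("disordering" the gene–function links); detection
counts under disordered links behave like the nominal level, which the
test suite checks.

## Reliability benchmarking

A method's output on a dataset is reduced to its p < 0.05 gene
selection, its FDR < 0.05 gene selection, and the functions detected on
the former. Against a reference method (the z-test by default):

* **relative specificity** = detected-function count ratio;
* **relative sensitivity** = relative specificity × FDR-gene count,
  normalized by the reference's product;
* **relative reproducibility** = mean, over detected function
  *instances* (function–dataset pairs), of the function's cross-dataset
  occurrence count, normalized by the reference's statistic. Averaging
  over instances (rather than unique functions) weights repeatedly
  detected functions by their recurrence; the per-unique-function
  alternative is available as an option.

HM contributes its single joint selection to both the p and FDR roles
(it has no FDR notion). Undefined ratios (reference count 0, or a
method detecting nothing anywhere) are reported as flagged NaN, never
silently zero. The reference method scores exactly 1 on all three
measures by construction — that is the normalization, and a test pins
it.

**Detection rate** of a designated list of disease-specific functions
is the per-dataset fraction detected, averaged over datasets (the
union-across-datasets alternative is an option). **AUC** compares a
method's function ranking — by ascending enrichment p on its own p <
0.05 selection, functions without a p tied at the bottom, midrank
ties — against the reference's detected-function set, as a
Mann–Whitney statistic; AUC < 0.5 flags the contrast as misanalyzed.
The ranking convention is the minimal one consistent with "functions
derived from a selection"; AUC is invariant to any order-preserving
transformation of the scores.

**Progressive degradation** validates the function-count specificity
proxy: for a paired design with P test–control pairs, replicate i
(i = 0..P) has the intensities of each array in its first i pairs
independently permuted across genes. Permutation preserves each array's
value distribution but destroys gene identity, so ranking specificity
decays progressively and detected-function counts (from the p < 0.05
selection and from fixed top-5/10/15% ranking slices) decline with i.

## Synthetic data

The generator emulates the two data regimes the model distinguishes.

* **Type I** (genetically identical samples): array = template +
  per-array N(0, σ²_i) noise; with no planted DEGs this is exact null
  data. Per-gene pooled SDs then follow σ·√(χ²_df/df), which a KS test
  confirms.
* **Type II** (heterogeneous cohorts): additionally, the test cohort is
  partitioned evenly into latent subtypes; each subtype shifts its own
  disjoint block of genes by per-gene signed amounts. This produces the
  diagnostic pattern — per-gene variance rank-correlated with
  |fold-change| — and vanishes continuously as the shift range goes to
  zero (bit-identical reduction to type I, by giving every random
  ingredient its own seeded substream).

Defaults: 10,000 genes; template N(7, 2²) clipped to [2, 15] log2
units, spanning a realistic array intensity range; triplicate cohorts
(the smallest design the pairwise estimator meaningfully supports, and
the canonical small-study size); error SD 0.2 log2 (a typical per-array
technical spread; per-sample values configurable to exercise sample
weighting); DEG fraction 0.1 with signed effect sizes |δ| ~ U(0.3, 2.0)
— deliberately including effects below the |FC| > 1 cutoff, because
coordinated modest shifts are exactly the biology fold-change cutoffs
miss; 2 subtypes of 250 genes each with shifts |β| ~ U(0.5, 2.0)
applied to the test cohort (disease-side heterogeneity). Gene-set
structure: 50 sets of 20 genes, 20% "signal" sets drawing 90% of their
members from the DEG pool, the rest uniform decoys; signal sets are
hypergeometrically enriched in true DEGs by construction.
`simulate_study` reuses one planted biology across replicate datasets
with independent noise — the substrate for reproducibility scoring.

For the degradation demonstration the template SD is set to 0.5: a
whole-array permutation injects noise on the template's scale, and with
the default spread of 2 log2 units a single permuted pair already
obliterates the contrast, turning the progressive decline into a cliff
(and a tie-ridden rank statistic). A moderate spread matches the
homogeneous cell-line setting this validation emulates and yields the
graded decline.

What the generator does **not** emulate: probe-level effects and
background, intensity-dependent (heteroscedastic-in-mean) noise,
correlation between genes beyond the planted blocks, batch structure,
and missing values. Passing tests therefore demonstrate correctness of
the estimators and the benchmarking logic under the stated model, not
performance on any particular real platform.

## Problem sizes

Test-suite and acceptance runs use 1,500–20,000 genes, 2–8 samples per
cohort, 20–50 Monte-Carlo replicates — sizes chosen so each statistical
check has comfortable power (3-SE bands for calibration, p < 0.01 for
rank correlations) while the whole suite stays interactive.

## Known limitations

* Subtype heterogeneity inflates within-cohort pairwise differences on
  the block genes, so a few percent of samplewise error SD is
  over-estimated on strongly heterogeneous cohorts (visible in the
  README example: 0.27 estimated vs 0.20 generated on the subtype-
  bearing side). This biases the z-test conservative, never
  anticonservative.
* The z-test treats the estimated σ²_i as known. With ≥ thousands of
  genes the estimation error is negligible (relative SE ≈ √(2/G)); on
  very small gene panels the normal reference would be optimistic.
* Two-cohort contrasts only; no multi-group designs.
* No missing-data mechanism: non-finite values are rejected at the
  door.
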