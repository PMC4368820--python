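# hta

Differential expression testing for two-cohort transcriptomic contrasts
with **samplewise** error-variance estimation, plus a benchmarking
platform that scores DE methods by the biological coherence and
cross-dataset reproducibility of what they detect.

## The problem

Gene-wise variance estimators (the two-sample *t*-test and its
derivatives) conflate two very different sources of spread. Technical
error is independent of differential expression and, per array, is well
described by additive Gaussian noise on the log2 scale. *Molecular
heterogeneity* — latent subtypes within a genetically diverse cohort,
each dysregulating its own pathway — inflates the variance of exactly
the genes that are differentially expressed, in proportion to their
fold-change. A *t*-test mistakes that inflation for noise and
deprioritizes the most interesting genes; more samples do not fix the
ranking. With only a handful of replicates per cohort the gene-wise
variance estimate is additionally so noisy that rankings shuffle by
chance.

## The method

Error variance is treated as homogeneous across genes but heterogeneous
across replicate arrays. For a cohort of n arrays, the variance across
genes of the per-gene log2 difference between arrays *i* and *j*
decomposes under Gaussian error as

    σ²_{ij} = σ²_i + σ²_j,

so each array's error variance is estimated by pooling its pairs:

    σ²_i = ½ · 1/(n−1) · Σ_{j≠i} σ²_{ij}.

Each measurement then carries a Gaussian PDF (measured value as mean,
its array's σ²_i as variance); multiplying a cohort's Gaussians per gene
gives the precision-weighted posterior N(μ, σ²) of the cohort mean with
σ² = 1/Σ(1/σ²_i). The fold-change posterior is
N(μ_t − μ_c, σ²_t + σ²_c), tested with

    z = (μ_t − μ_c) / √(σ²_t + σ²_c),

two-sided against the standard normal, with Benjamini–Hochberg FDR
across genes. Because the estimation pools all genes, it is accurate
even for triplicates, is invariant to per-array scaling normalization,
and never mistakes subtype-driven spread in a single gene for error.

The package also provides the comparison baselines (pooled *t*-test;
the hybrid rule p < 0.05 & |log2 FC| > 1), Fisher-exact gene-set
overrepresentation, a reliability benchmark (relative specificity /
sensitivity / reproducibility, disease-function detection rate, AUC
against a reference method's function set), and a synthetic-data
generator that plants known DEGs, latent subtypes and functional
structure.

## Worked example

```python
from hta import HTAModel, bmorr_report
from hta.simulate import SyntheticConfig, simulate_study

cfg = SyntheticConfig(n_features=5000, n_test=4, n_control=4,
                      n_subtypes=2, deg_fraction=0.1,
                      subtype_block_size=150, seed=7)
datasets, truth = simulate_study(cfg, n_datasets=2)
matrix, design = datasets["dataset_0"]

res = HTAModel(matrix, design).fit()
print(res.summary())
```

```
Heterogeneity-tolerant differential expression (z-test)
========================================================
features: 5000   test n=4   control n=4
selected p<0.05: 805    selected FDR<0.05: 675
samplewise error SD (log2):
  t1: 0.2724
  t2: 0.2762
  t3: 0.2749
  t4: 0.2751
  c1: 0.1997
  c2: 0.2018
  c3: 0.1996
  c4: 0.1991
scaling normalization target (grand mean log2): 6.9680
```

Every array was simulated with error SD 0.2; the control estimates
recover it almost exactly, while the test-cohort estimates are slightly
inflated because the planted subtype blocks (6% of genes, shifted in
half of the test cohort) leak a little into the pairwise differences.
`res.frame` holds the per-gene table (`fc_hat`, `var_fc`, `z`, `p`,
`q`); note `var_fc` is one number for all genes, so the z-ranking is
exactly the fold-change ranking here.

Benchmarking three methods on the two replicate datasets against the
z-test as reference:

```python
report = bmorr_report(datasets, ["hta", "ttest", "hm"], truth.collection,
                      disease_functions=sorted(truth.signal_sets))
print(report.per_method.round(3).to_string())
```

```
        RSP_mean  RSE_mean     RR   DRF
method
hta         1.00     1.000  1.000  1.00
ttest       1.00     0.633  1.000  1.00
hm          0.65     0.286  0.885  0.65
```

The reference rows are 1 by construction. On this heterogeneous data
the *t*-test matches the z-test's function specificity but passes far
fewer genes at FDR < 0.05 (relative sensitivity 0.63), and the hybrid
fold-change cutoff misses a third of the planted signal functions
(detection rate 0.65).

A command-line interface mirrors the library
(`hta simulate | test | baseline | enrich | bmorr | degrade`); see
`hta --help`.

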