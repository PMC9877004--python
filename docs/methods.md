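# Methods

This note documents the models, estimators and design choices behind
`wbgr`, in the order the pipeline runs them.

## Globin-dominance metrics

For sample *j* with column total *N_j*, each hemoglobin-registry gene *i*
contributes α_i = count_ij / N_j; the globin share is N_G = Σα_i and the
globin noise reduction index is N_G_RI = (1 − N_G)/N_G. N_G_RI is a
monotone-decreasing transform of the globin share: it is the ratio of
informative (non-globin) to globin reads, 1.0 at a half-globin library and
+∞ at zero globin reads (reported as `inf` with a warning rather than an
error, since perfectly depleted small libraries can legitimately contain
no globin read).

The default registry holds 15 genes: the ten protein-coding hemoglobin
subunit genes (HBA1, HBA2, HBB, HBD, HBE1, HBG1, HBG2, HBM, HBQ1, HBZ)
plus five hemoglobin pseudogene symbols. Annotation releases differ on
pseudogene naming, so the registry is a plain-text file and fully
user-overridable; every downstream formula depends only on the aggregate
share, not on the membership split.

Pre/post comparisons are paired by donor: a two-sided paired t-test on
per-donor N_G_RI differences. Exactly zero variance of the differences
(e.g., at depletion efficiency 0) yields p = 1.0 with a warning rather
than an exception. Pre/post expression concordance is the per-donor
Pearson correlation of log2(CPM + 1) over genes outside the registry; CPM
rather than size-factor normalization because the comparison is a
within-pair descriptive metric and must be invariant to the depth shift
depletion introduces. Abundance binning tallies genes per sample into
half-open bins [5,20), [20,100), [100,500), [500,2000), [2000,5000),
[5000,10000), [10000,∞); genes under 5 counts are not binned. Half-open
intervals are forced by the abutting bin labels (20 is both an upper and a
lower label), and the lower cutoff of 5 matches the first category.

## The synthetic cohort model

The generator's job is to reproduce the statistical structure that makes
globin depletion matter, with known ground truth.

**Composition.** Each sample draws a globin share f ~ Uniform[0.200,
0.626] (the observed pre-depletion range; the default depletion efficiency
0.995 takes the whole range below 1%, since r·f/((1−f)+r·f) ≤ 0.0085 at
f = 0.626 with r = 0.005). The globin pool occupies share f of the tube,
split across the 15 registry genes by fixed proportions dominated by HBB,
HBA2 and HBA1; the split is a config default because only the aggregate
matters downstream. The non-globin transcriptome starts from a log-normal
baseline (mean 4, sd 2 on the log2 scale — wide enough to populate all
seven abundance bins at a 2×10⁷-read library), multiplied by planted
effects: GBM samples multiply their effect genes by 2^log2fc with |log2fc|
drawn from [1, 3] (fold change at least 2), female samples multiply sex
genes by 2^1. Effect and sex genes are disjoint and never globin.

**Noise.** The model is gamma–multinomial: the tube's realized relative
abundances are the expected non-globin composition times unit-mean gamma
noise with CV² equal to the configured dispersion (0.05 by default, a
typical bulk RNA-seq biological CV of ~22%), and the library is a single
multinomial draw of exactly `library_size` reads from the realized
composition. Marginally this is the standard negative-binomial count model
with the configured dispersion, and every column sums to the library size
exactly — sequencing capacity, not input RNA, is the binding constraint.
Gamma noise is applied to the non-globin block only: donor-to-donor
variation in globin content is already modeled by the per-sample draw of
f, so the realized globin share fluctuates binomially around f.

**Depletion.** In-silico globin reduction acts where the laboratory step
acts: on the RNA aliquot before sequencing. The sample's realized
composition has its globin components thinned to retention (1 −
efficiency) and renormalized, and the post library is an independent
multinomial draw of the same library size from the depleted composition.
Pre and post therefore share the tube's biological state and differ only
by depletion and sequencing sampling. This is the mechanism that makes
depleted libraries genuinely more informative: the capacity freed from
globin reads is spent sampling the non-globin transcriptome more deeply.
(Thinning the *realized pre-GR count matrix* and resampling it instead
would produce a post library that is a noisier copy of the pre library —
by construction it could never yield more significant genes, which is the
opposite of the phenomenon under study.)

**Other layers.** The miRNA generator is the same model without globin
genes over a smaller universe (800 species, 2×10⁶ reads), with planted
effects at least 2.5-fold, matching that assay's thresholds. Tissue-cohort
DEG tables contain an exact seeded fraction of the blood-planted genes
with concordant directions plus cohort-private decoys, FDRs below the
declared cutoff. Module frameworks designate "hot" modules drawing a
configurable fraction of their genes from planted effects of one
direction. The qPCR generator emits triplicate Ct values: reference genes
at a constant expected Ct, targets offset by a baseline ΔCt and lowered by
the planted log2fc in GBM samples (one PCR cycle per twofold), Gaussian
replicate noise on top. At zero noise the ΔΔCt analysis inverts the
generator exactly.

**What the generator does not emulate.** Read-level artifacts (GC bias,
mappability, duplicates), correlated gene modules in the baseline
(baseline expression is drawn independently per gene, so module scoring is
tested against planted enrichment rather than emergent co-expression),
library-preparation batch effects, and count outliers. Passing tests
therefore demonstrate correctness of the estimators under a clean NB
model, not robustness to every artifact of real libraries.

## Differential expression

The stage mirrors the standard count-based workflow. Genes are kept when
their CPM exceeds 1 (strictly) in at least two samples, CPM computed on
raw column totals. Size factors are median-of-ratios: for each gene with
positive counts in every sample, its count is divided by its
across-sample geometric mean, and a sample's factor is the median of those
ratios. (Scaling one sample's counts by c scales its factor by c *relative
to the others*; the geometric-mean reference absorbs c^(1/n), so the
invariance is in factor ratios and normalized counts up to a constant
shared by all samples.) Visualization matrices are log2(count/factor + 1),
optionally centered on the control-group mean per gene.

The test is an in-package negative-binomial Wald test, fitted for all
genes at once:

- **Model.** Per gene, counts follow an NB log-linear model with offset
  log(size factor) and covariates intercept, group (GBM vs control) and
  sex (included when both sexes are present; a sex column aliased with
  group raises a design error naming the term).
- **Dispersion.** Per-gene method of moments on residuals about a
  first-stage Poisson fit: α̂ = Σ_j[(y_j − μ̂_j)² − μ̂_j]/μ̂_j² divided by
  the residual degrees of freedom, floored at 1e−8, no shrinkage across
  genes. Estimating about the fitted model rather than the marginal mean
  keeps real group effects out of the dispersion (a marginal-variance
  estimator absorbs the effect being tested and destroys power on true
  positives).
- **Fitting.** Iteratively reweighted least squares vectorized across
  genes through the shared design matrix (weights μ/(1 + αμ), up to 50
  iterations, convergence at 1e−8, linear predictor clipped to ±30, a
  1e−10 ridge on the normal equations for numerical safety).
- **Inference.** Wald statistic on the group coefficient, standard error
  from the inverse expected information, referred to a t distribution with
  n − p degrees of freedom. The t reference is a small-sample correction:
  with ~12 samples a normal reference is visibly anticonservative, and
  null simulations with the t reference put the p ≤ 0.05 fraction at
  ≈ 0.05 (the test suite checks [0.03, 0.07] over ten seeded null
  cohorts). log2fc is the group coefficient divided by ln 2.
- **Degenerate genes.** A gene with an all-zero group has a divergent
  group MLE; those genes are refit with a 0.5 pseudo-count on all samples
  and flagged (`pseudo` column). Genes constant across all samples report
  log2fc 0 and p 1.

Benjamini–Hochberg adjustment uses the standard step-up (via statsmodels;
the test suite checks it against a brute-force min_{j≥i} m·p_(j)/j
oracle). Significance thresholds are inclusive exactly as printed: mRNA
calls need 2^|log2fc| ≥ 2.0 and FDR ≤ 0.05; miRNA calls need 2^|log2fc| ≥
2.5 and raw p ≤ 0.05. Fold-change cutoffs apply to the raw (unshrunken)
estimate.

## Module scoring and evidence integration

A module's score is x − y, where x (y) is the percentage of its *tested*
transcripts — module genes present in the post-filter universe — called
significantly up (down) under the assay's thresholds. Untested transcripts
cannot be significant, so they are excluded from the denominator. The
module-level test is a two-sided Fisher exact test of significant-vs-not
membership inside vs outside the module, BH-corrected across modules and
flagged at FDR ≤ 0.05. Fisher-plus-BH is a deliberate minimal choice: it
is exact at small module sizes and reproducible, and the test suite
validates it as ≈ 0 false modules on random frameworks. A hypergeometric
enrichment test ignores directionality by design; the direction lives in
the score.

Evidence integration counts, per blood DEG, the number of sources
(blood + each tissue cohort table) containing the gene; direction
consistency is required by default, since the biological claim is
concordant dysregulation in blood and tumor. Genes reaching support ≥ 2
are retained. External tables carry their own declared thresholds — the
loader derives direction from the sign of log2fc (exactly 0 maps to
"none" and drops out of direction-aware sets) and does not re-derive
significance. miRNA-target overlap admits experimentally validated
interactions only; predicted-only rows are ignored. Pathway-result
filtering keeps rows with FDR < 0.1 and fold enrichment > 1.4, both
strict as printed.

## Panel selection and qPCR validation

Candidate frequency is the fraction of GBM samples whose control-centered
log2 expression moves past a margin (default 0.5 log2 units) in the gene's
DEG direction. The margin rule is direction-aware and scale-free, and
reduces to a sign rule at margin 0; frequencies are non-increasing in the
margin. Candidates must exceed 50% frequency (strict). The panel must stay
more than half upregulated: while the up-share does not clear the bound,
the lowest-frequency down-gene is dropped (ties broken by smaller
|log2fc|, then reverse-lexicographic id); the boundary itself counts as
failing, so any trimming ends strictly above one-half, and an untouched
panel always satisfies up-share ≥ one-half. With a target size, the
top-frequency candidates are kept subject to the same constraint, ties by
larger |log2fc| then lexicographic id.

ΔΔCt quantification averages triplicates on the Ct scale (the standard
convention; averaging 2^−Ct instead would weight early-cycle outliers),
references each target against its RNA class's housekeeping gene
(mRNA→GAPDH, miRNA→U6, lncRNA→18S, overridable), and centers ΔCt on the
control-group mean, so fold change = 2^−ΔΔCt, log2fc = −ΔΔCt, the
control group means to zero, and every reference gene's fold change is
exactly 1. Group comparisons are one-sided two-sample t-tests oriented by
the marker's expected direction recorded at selection time; degenerate
identical groups report p = 0.5 with a warning. Patient panel profiles
report, per patient and specimen, each panel gene's log2 value (missing
genes as gaps, never zeros) and their sum, the stacked "overall panel
expression scale".

## Problem sizes and determinism

Simulation-based checks run at desk scale, chosen so each property is
measured where it is informative: concordance and depletion-share checks
at one to ten donors with 10,000 genes and 2×10⁷ reads (the regime where
the log-normal baseline populates all abundance bins); power and
calibration studies at 6 + 6 donors with 2,000 genes at 2×10⁵–2×10⁶
reads — the shallow end, where depth actually limits detection and the
pre/post sensitivity gap is visible; effect-recovery studies over 50
seeded cohorts of 1,000 genes. Every stochastic component takes an
explicit integer seed, and identical seeds give byte-identical outputs.

## Known limitations

- Dispersion is estimated per gene without cross-gene shrinkage; at very
  small n the estimates are noisy, which the t reference compensates in
  aggregate but not per gene. Exact replication of shrinkage-based
  pipelines' p-values is out of scope.
- The moment dispersion estimator is unweighted across samples; with
  extreme size-factor spread a weighted estimator would be more efficient.
- The panel-selection frequency rule operates on control-centered
  normalized expression; with very few control samples the centering
  itself is noisy and the margin should be raised.
- The simulator draws baseline expression independently per gene; module
  co-expression exists only where planted.
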