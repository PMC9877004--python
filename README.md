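# wbgr — whole-blood globin-reduction transcriptomic analysis

Whole blood is an attractive liquid-biopsy substrate for brain tumors such
as glioblastoma (GBM), but hemoglobin mRNAs dominate blood RNA-seq
libraries — routinely 20–63% of all reads in a sample — drowning the
informative transcriptome in globin background. Globin reduction (GR)
depletes those transcripts before sequencing, and because sequencing
capacity is fixed, every removed globin read is replaced by an informative
one. `wbgr` implements the analysis stack built around that idea, for
bioinformaticians who want to quantify globin dominance, run the
blood-specific differential-expression workflow, and push candidate
markers through to qPCR validation — all exercisable end to end on a
bundled synthetic-data generator, with no external downloads.

## The statistics at the core

For a sample with total counts *N* and hemoglobin-registry gene counts
*n<sub>i</sub>* (15 Ensembl hemoglobin-related genes by default), each gene
contributes a read fraction α<sub>i</sub> = n<sub>i</sub>/N. The sample's
globin share and globin **n**oise **r**eduction **i**ndex are

```
N_G    = Σ α_i                    (globin share of the library)
N_G_RI = (1 − N_G) / N_G          (informative-to-globin read ratio)
```

Depletion with efficiency *e* (retention r = 1 − e) moves a pre-depletion
share *f* to r·f / ((1 − f) + r·f) in expectation, so e = 0.995 takes the
whole 20–62.6% range below 1%.

Around these metrics the package provides:

- **`core_io`** — validated readers/writers for count TSVs, sample sheets,
  GMT module files, DEG tables, miRNA-target tables and qPCR Ct CSVs.
- **`synthetic_data`** — a gamma–multinomial (negative-binomial) simulator
  of globin-dominated whole blood with planted group/sex effects, in-silico
  depletion under fixed sequencing capacity, plus miRNA, tissue-cohort,
  module-framework and qPCR generators, all seed-deterministic with
  recorded ground truth.
- **`globin_metrics`** — α_i / N_G / N_G_RI, paired pre/post t-tests,
  per-sample abundance-bin tallies, and pre/post expression concordance on
  non-globin genes.
- **`dge`** — CPM > 1 in ≥ 2 samples filtering, median-of-ratios size
  factors, a per-gene negative-binomial Wald test with sex adjustment,
  Benjamini–Hochberg FDR, and the blood thresholds (mRNA: FC ≥ 2.0 and
  FDR ≤ 0.05; miRNA: FC ≥ 2.5 and p ≤ 0.05).
- **`enrichment_integration`** — blood-module scoring (score = %up − %down
  among tested transcripts, Fisher-exact module significance at FDR ≤
  0.05), multi-cohort evidence integration with the ≥ 2-source retention
  rule, validated miRNA-target overlap, and the pathway-result filter
  (FDR < 0.1, fold enrichment > 1.4).
- **`panel_qpcr`** — frequency-based marker-panel selection (> 50%
  direction-consistent GBM samples, panel at least half upregulated),
  2^−ΔΔCt quantification against class-specific reference genes
  (GAPDH/U6/18S), one-sided group tests, and per-patient stacked panel
  profiles. Ships the 10-marker "GBM-Dx" panel fixture (7 mRNA, 1 lncRNA,
  2 miRNA).

A `wbgr` command-line tool wraps each stage (`wbgr simulate`, `wbgr dge`,
`wbgr modules`, `wbgr qpcr`, ...).

## Worked example

```python
from wbgr import synthetic_data as synth, globin_metrics as gm, dge

cfg = synth.SynthConfig(n_control=6, n_gbm=6, library_size=2_000_000,
                        n_genes=2000, n_de_genes=60, seed=1)
pre, sheet, truth = synth.simulate_blood_cohort(cfg)
post = synth.simulate_globin_depletion(pre, truth, efficiency=0.995, seed=2)
post_sheet = synth.post_sample_sheet(sheet)
pairing = synth.combined_sample_sheet(sheet, post_sheet)

registry = gm.default_globin_registry()
paired = gm.summarize_ngri_paired(gm.compute_globin_stats(pre, registry),
                                  gm.compute_globin_stats(post, registry),
                                  pairing)
print(f"mean globin share: pre {paired.mean_pre_ng:.1%}, post {paired.mean_post_ng:.2%}")
print(f"mean N_G_RI: pre {paired.mean_pre_ngri:.2f}, post {paired.mean_post_ngri:.1f} "
      f"(paired t p = {paired.p_value:.2e})")
conc = gm.concordance_pre_post(pre, post, registry, pairing)
print(f"min per-donor concordance R = {conc.min():.4f}")

table = dge.fit_nb_dge(dge.filter_low_expression(post), post_sheet)
degs, n_up, n_down = dge.apply_thresholds(table, dge.MRNA_THRESHOLDS)
hits = len(set(degs.index) & set(truth.de_genes))
print(f"{len(degs)} DEGs ({n_up} up, {n_down} down); "
      f"{hits}/{len(truth.de_genes)} planted genes recovered")
```

Output:

```
mean globin share: pre 43.9%, post 0.44%
mean N_G_RI: pre 1.62, post 326.2 (paired t p = 6.44e-04)
min per-donor concordance R = 0.9945
57 DEGs (28 up, 29 down); 57/60 planted genes recovered
```

Depletion drops the globin share two orders of magnitude, lifts the
noise-reduction index from ~1.6 to ~330 while leaving non-globin
expression essentially unchanged (R > 0.99), and the downstream
negative-binomial test recovers 57 of 60 planted twofold-plus effects at
FC ≥ 2 and FDR ≤ 0.05.

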