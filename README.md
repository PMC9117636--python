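# epicrosstalk

Epigenetic-crosstalk analysis of gastric cancer: a tested, reusable
implementation of the pipeline that links histone (H3K4me1, H3K4me3,
H3K27ac) and RNA (m6A) modification patterns to patient subtypes, survival
and immunotherapy response.

It is intended for computational-biology users who have pre-called
modification site tables (DiffBind / exomePeak2-style output), a gene
annotation, and gene × sample expression matrices with clinical metadata —
and want to run, test or extend this analysis without re-deriving its many
unstated details. A full synthetic-data generator emulates every input, so
the whole pipeline is exercisable and testable offline.

## What it computes

- **EMRG / EMRL catalog.** A gene is *epigenetic-modification-related*
  when (1) a differential histone site (|FC| > 1, p < 0.05) sits in its
  promoter (TSS ± 3 kb) with a same-direction differential expression
  (|log2FC| > 1, p < 0.05) in the same cell line, or (2) an m6A site sits
  in the gene and the gene correlates with an m6A regulator (ρ > 0.3 with
  a writer/reader, or ρ < −0.3 with an eraser; BH-adjusted p < 0.05).
  EMRLs are the lncRNA members.
- **EMD subtype.** Candidate EMRLs are screened by univariate Cox
  regression (p < 0.01) and samples are consensus-clustered (k-means,
  Euclidean, 1000 resamples, k ≤ 7) on the screened EMRLs; the cluster
  with the worst Kaplan–Meier survival is the
  *epigenetic-modification-dysregulated* (EMD) subtype.
- **EMD score.** From DEGs between the EMD and best-survival clusters,
  up/down signatures set1/set2 are selected by gene-significance and
  module-membership thresholds; per sample,

  ```
  EMD score = log2( ssGSEA(set1) / ssGSEA(set2) )
  ```

  with both single-sample enrichment scores min–max rescaled into
  (0.01, 1] per cohort before the ratio. The score recognizes the EMD
  subtype (ROC/AUC), stratifies survival at the cohort median (log-rank),
  and contrasts immunotherapy response rates at the lower-quartile split
  (Fisher exact). The **FTO/HDAC1 ratio** (log2-scale expression
  difference of the m6A eraser FTO and histone deacetylase HDAC1) is a
  two-gene proxy of the same axis.

See `docs/methods.md` for the model details, numerical conventions and
what the synthetic data does and does not emulate.

## Worked example

```python
from epicrosstalk import SimulationConfig, simulate_cohort, EMDSubtypeModel

cfg = SimulationConfig(seed=7, effect_size=3.0, noise_sd=0.5, n_samples=120)
cohort = simulate_cohort(cfg)                      # annotation, sites, expression, clinical
model = EMDSubtypeModel(cohort.expression,         # genes x samples + survival metadata
                        cohort.design.emrl_panel,  # candidate EMRLs
                        k=4)
results = model.fit(seed=7)
print(results.summary())
```

prints

```
EMD subtype model
============================================================
Survival screen: 19/28 candidate EMRLs pass at p < 0.01
Consensus clustering: k = 4 (PAC: k=2: 0.000, k=3: 0.000, k=4: 0.240, k=5: 0.318, k=6: 0.354, k=7: 0.352)
Cluster sizes: C1: 30, C2: 30, C3: 15, C4: 45
EMD cluster: C1 (worst survival); reference: C2 (best survival)
          n  events  survival_at_t_common
cluster
1        30      27              0.000000
2        30      10              0.887496
3        15       6              0.779221
4        45      17              0.768454
Signature: |set1| = 42, |set2| = 33 (GS >= 0.4, MM >= 0.7)
EMD-score AUC for recognizing the EMD cluster: 1.000
Median-split log-rank: chi2 = 15.07, p = 0.000104
ICI response (low vs high score, Q1 split): 73% vs 46% (Fisher p = 0.011)
```

Reading it: 19 of the 28 planted modification-related lncRNAs are
survival-associated; clustering on them recovers four patient clusters;
cluster C1 (all 30 planted EMD-like samples) has the worst survival and is
designated EMD; the selected 42/33-gene signature yields an EMD score that
recognizes the subtype perfectly (AUC 1.0), separates survival at the
cohort median (log-rank p ≈ 1e-4), and shows the lower response rate in
high-score patients.

Lower-level pieces are importable directly — e.g.
`classify_site_region(site, gene)` for promoter/UTR/exon assignment,
`emrg_criterion1/2` + `build_catalog` for the catalog,
`ssgsea`, `emd_score`, `fto_hdac1_ratio`, `km_logrank`, `score_auc`,
`response_contrast` — and a CLI (`epicrosstalk simulate|emrg|de|ceg|comut|
coxscreen|pipeline`) operates on fixture directories.

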