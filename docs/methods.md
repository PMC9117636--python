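# Methods

## Scope and model

`epicrosstalk` implements a desk-scale version of an epigenetic-crosstalk
analysis of gastric cancer. The analysis chain is:

1. **Peak-to-gene assignment.** Differential histone-modification sites
   (H3K4me1, H3K4me3, H3K27ac; DHMS) and m6A sites (MMS) — consumed as
   pre-called tables with signed fold-change and p-value — are classified
   against a gene annotation. The promoter is TSS ± 3 kb; region labels
   follow the fixed precedence promoter bins (<1 kb, 1–2 kb, 2–3 kb) >
   3′UTR > CDS > exon > intron > distal. Promoter bins are assigned by the
   minimum base-to-TSS distance of the site, which resolves sites that
   straddle bin boundaries.
2. **EMRG calling.** A gene is epigenetic-modification-related (EMRG) when
   (criterion 1) a DHMS (|fold-change| > 1, p < 0.05) lies in its promoter
   and the gene is differentially expressed (|log2FC| > 1, p < 0.05) in the
   same direction in the same cell line; or (criterion 2) an MMS lies in
   the gene in ≥ 1 cell line and the gene's expression correlates with an
   m6A regulator — positively (ρ > 0.3) with a writer/reader or negatively
   (ρ < −0.3) with an eraser (ALKBH5, FTO), at BH-adjusted p < 0.05.
   "In the gene" is read as the transcribed region (exon union, including
   the 3′UTR) or the promoter window; both readings appear in the binned
   site-distribution summaries, and a deterministic definition is required
   for reproducible counts. EMRLs are the lncRNA members of the catalog.
3. **Subtype discovery.** Candidate EMRLs are screened by univariate Cox
   regression (Wald p < 0.01, Breslow ties). Samples are consensus-clustered
   on the z-scored screened EMRLs: for each k in 2..7, 1000 resamples of
   80% of samples are k-means-clustered (Euclidean, k-means++ seeding, 10
   restarts); consensus(i,j) = co-cluster count / co-sample count; final
   labels come from average-linkage hierarchical clustering of
   1 − consensus. k is chosen by minimum PAC over the (0.1, 0.9) window
   unless fixed (the analysis fixes k = 4). The cluster with the lowest
   Kaplan–Meier survival at the last common follow-up time is the EMD
   (epigenetic-modification-dysregulated) subtype; the best-survival
   cluster is the reference.
4. **EMD score.** DEGs between the EMD and reference clusters (Welch test
   on log2 values, |log2FC| > 1, p < 0.05, BH-adjusted p reported) are
   partitioned by the sign of their correlation with the EMD indicator
   (gene significance, GS). Each sign group gets a first-principal-
   component eigen-profile; module membership (MM) is each gene's
   correlation with it. set1 = positive-GS genes with GS ≥ 0.4 and
   MM ≥ 0.7; set2 symmetrically for negative GS. Per sample,
   EMD score = log2(ssGSEA(set1) / ssGSEA(set2)).
5. **Read-outs.** Cohort-median score split → KM curves + log-rank;
   ROC/AUC of the score against the EMD label; lower-quartile (Q1) split
   of scores → responder-rate contrast with the two-sided Fisher exact
   test; FTO/HDAC1 ratio = log2-scale expression difference.

## Key numerical choices

- **Coordinates** are 0-based half-open internally; GTF is converted on
  read/write. Sites on absent chromosomes classify as distal, not errors.
- **ssGSEA** ranks genes by expression descending, ties broken by gene
  identifier. In-set step weights are |rank-normalized expression|^α
  (α = 0.25 by default), normalized to sum to 1 over the set; each
  out-of-set gene steps 1/(N − |S|). The score is the integrated running
  sum (sum of cumulative differences), not the maximum deviation. At α = 0
  the score depends only on ranks and is invariant under any strictly
  monotone transform of the sample's expression.
- **Rescaling before the ratio.** Raw enrichment scores can be negative,
  which would make the log2 ratio undefined. Both score vectors are
  min-max rescaled into (ε, 1] with ε = 0.01, per cohort by default
  (cohorts may sit on different scales); a global mode exists for
  single-cohort or tiny-cohort inputs. Samples exactly at the cohort
  median score go to the low group.
- **Cox fitting** maximizes the Breslow partial likelihood by
  Newton–Raphson with step halving; non-convergent or zero-information
  fits are reported with a convergence flag and never pass the screen.
  Constant-expression candidates are excluded with a warning.
- **Degenerate inputs.** Genes with zero variance in both DE groups and
  equal means get p = 1; co-mutation pairs where a gene is mutated in no
  or all samples get degenerate records with p = 1; constant genes are
  dropped from correlation screens with a warning.
- **Consensus clustering determinism.** Samples are canonically ordered
  by id before any RNG use, so results at a given seed are invariant to
  input column order. With subsample fraction 1 and a deterministic
  k-means seeding, the consensus matrix is exactly binary — a structural
  check used in the tests.
- **Quantiles.** Q1 and medians use linear-interpolation (type-7)
  quantiles; boundary samples go to the low group.

## The synthetic cohort

The generator emulates every input the pipeline consumes, with the
statistical structure the analysis assumes. Defaults: 300 genes (25%
lncRNA) tiled ≥ 12 kb apart on one toy chromosome (so ±3 kb promoters
never collide), 120 patients in four equal clusters, log2 effect size 2,
noise SD 0.5, unit log-hazard per SD of the planted score, ρ = 0.8 planted
gene–regulator correlations.

- The last cluster is the EMD-like cluster: planted set1 genes (40
  protein-coding + 8 lncRNAs) are shifted +effect, set2 genes (30 + 8
  lncRNAs) −effect, FTO and ALKBH5 up, HDAC1/HDAC2/KDM1A down. Each other
  cluster is elevated on its own 4-lncRNA marker block; without these
  blocks the three non-EMD clusters would be statistically identical and
  no method could recover four clusters.
- Planted sites are placed in promoters (histone) or 3′UTR/exon (m6A) with
  |fold-change| > 1 and p < 0.05, with direction-matched cell-line DEG
  records; background sites are intergenic with sub-threshold fold-changes.
- Survival is exponential with log-hazard = log(log2/median) +
  hazard_coef × standardized planted score (median 730 days), independent
  uniform censoring on (31, 1825] days, and event times ≤ 30 days
  resampled (the cohort exclusion rule). The exponential's memorylessness
  keeps the Cox coefficient identifiable under this truncation.
- Responder probability is logistic-decreasing in the planted score
  (slope 1.5), giving ≈ 90% response at z = −1.5 and ≈ 10% at z = +1.5.
  On the default 120-sample cohort the Q1-split contrast is modest
  (roughly 60–75% vs ≈ 46%), because most above-Q1 samples are non-EMD;
  a steep contrast like the reference cohorts' needs a cohort whose score
  spread is dominated by the subtype axis.
- Mutations: 43 regulator genes mutate independently at rate 0.15;
  configured co-mutated pairs are drawn jointly with the requested odds
  ratio via the standard margins-plus-odds-ratio (Plackett) construction.
- Every generator is a pure function of (config, seed); two runs are
  byte-identical after writing.

What passing tests on this cohort do **not** show: robustness to
batch effects across real cohorts, to count-level noise (inputs here are
clean log2 matrices), to annotation mismatches between assemblies, or to
the peak-calling upstream of the site tables — all of which are out of
scope by design.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at the sizes the properties are stated at:
120 samples for subtype recovery/scoring, 500 for hazard recovery and
median-split survival (50 replicates per arm), 200 for correlation
recovery, 500 genes for screen calibration. These sizes make every check
a few seconds to a couple of minutes on one core while keeping Monte-Carlo
tolerances honest.

## Known limitations

- The signature-selection step replaces full weighted co-expression
  network analysis (topological overlap, dynamic tree cut) with the
  sign-partition + eigen-profile GS/MM rule described above. It preserves
  the semantics (trait- and module-correlated genes) with a fully
  specified, testable rule; thresholds (0.4/0.7) are configurable because
  no canonical values exist.
- The published catalog sizes, AUCs and response rates depend on the
  original patient cohorts and full-scale ChIP/MeRIP processing and are
  not reproducible from synthetic data; this package reproduces the
  *computations*, and its acceptance checks are recovery and calibration
  properties on planted truth.
- Co-mutation significance is unadjusted (p < 0.05), matching the stated
  rule; with many regulators this implies a non-trivial family-wise error
  and results should be read as screening, not inference.
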