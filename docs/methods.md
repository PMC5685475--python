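# Methods

This note documents the models, conventions and design choices behind
`conswitch`, in the order data flows through the pipeline.

## Coordinates and formats

All genomic coordinates are 0-based half-open (BED convention)
internally; a TSS is a single base position. Count matrices are TSV
with a mandatory sidecar sample-metadata table (sample → day,
replicate) rather than metadata encoded in sample names, so the
day/replicate mapping is explicit and validated. Readers and writers
round-trip losslessly on valid input.

## Expression preprocessing

**RPKM.** `value = count · 1e9 / (gene_length · library_size)` with
library size the column sum. RPKM is linear in counts and invariant to
uniform depth scaling, which the tests assert. Note the identity
`Σ_genes rpkm · length = 1e9` per sample: the overall RPKM scale is
pinned by the size of the gene panel, which matters for threshold
grids (below).

**Outlier rule.** Each gene's single highest value across all samples
is *masked* (NaN), not the gene removed — the source analysis removes
one value per gene, and masking preserves the full day design; the
affected day averages the remaining replicates. Ties go to the first
sample in column order.

**Noise threshold.** For each candidate threshold t, genes whose
*maximum* day-mean is ≥ t are retained (a gene is "expressed" if it
ever exceeds t; a per-day filter would drop genes expressed on only
one side of the switch). The sample skewness g1 = m3/m2^{3/2} (biased
moment estimator, no small-sample correction) of log2 mean expression
over retained genes is computed; the chosen threshold minimizes |g1|,
ties to the smallest t. "Closest-to-symmetric" is evaluated on the
empirical distribution directly — no parametric curve is fitted, since
skewness is well-defined on the sample. The scan is implemented with
suffix cumulants over genes sorted by maximum day-mean (O(n) per
grid), and the tests check it against a direct per-candidate scan.
The default candidate grid steps by 0.005 RPKM from 0 up to the 95th
percentile of per-gene maxima: because of the RPKM identity above, a
fixed 0–5 window cannot bracket the abundance valley for every panel
size, so the grid adapts to the observed scale. The value 1.645 RPKM,
the optimum on the original 11k-gene cone data set, is kept as a
reference constant only — it is panel-specific, not a target.

**log2 with jittered pseudocount.** Zeros are replaced by the global
minimum nonzero value plus a uniform integer 1–10 divided by 1e6,
drawn per zero cell from a seeded generator, then everything is log2
transformed; the output is finite everywhere and reproducible under a
fixed seed. Pipeline stages are order-enforced (rpkm →
outlier_removed → day_mean → thresholded → log2); calling a stage out
of order raises.

## Switch detection

**Windows.** Pre = P0–P5, post = P7–P12. The switch day P6 is
transitional and belongs to neither window, in the fold change and in
the LRT groups alike.

**PCA** is computed on the 13 day-means (observations = days,
variables = genes, per-gene centering, SVD), matching the one-value-
per-day time-course reading of the analysis; running it on the 39
samples would mix replicate noise into the components. Sign
convention: each component is flipped so its earliest-day score is
≤ 0, making a switch-on-dominated PC1 rise. Scores × loadings
reconstruct the centered matrix to 1e-8.

**NB likelihood-ratio test.** Implemented natively rather than
delegated to an external count-model package, so the pipeline is
self-contained and the estimator fully specified: per gene a NB GLM
with log link and library-size offsets, full model = one mean per
group, null = common mean, fixed per-gene dispersion, LRT statistic
against χ²(1). Dispersion is the method-of-moments solution of
var = μ + φμ² on size-factor-normalized counts (pooled within groups),
shrunk 50/50 toward a 25%-trimmed-mean common dispersion and clipped
to [1e-10, 100]. Mean fitting is a vectorized Newton iteration on
log-rate (score Σ(y−μ)/(1+φμ)), which converges in a handful of steps;
below a dispersion floor of 1e-10 the Poisson log-likelihood is used
directly, and the statistic matches the closed-form Poisson LRT in
that limit. Calibration: at 30 + 30 samples the type-I error at
p < 0.05 sits within binomial error of 0.05 over 2,000 null genes; at
the pipeline's 18 + 18 windowed design it is mildly liberal (≈ 0.06),
which the |log2FC| ≥ 1 classification gate renders inconsequential
for class labels. All-zero genes get p = 1 and a flag. Multiple
testing is Benjamini–Hochberg throughout ("FDR" is otherwise
unspecified upstream), checked against scipy's implementation.

**Classes.** switch_on: log2FC ≥ 1 and FDR < 0.05; switch_off
mirrored; constant: |log2FC| < 0.01; other: the rest. The |log2FC| > 2
subset is flagged for fine time-course summaries. Classification is a
pure function of (log2FC, FDR) and idempotent.

**Chromosome distribution.** Pearson chi-square of observed
per-chromosome switch-gene counts against expectation proportional to
all expressed genes, pooling chromosomes with expected count < 5.

## Permutation enrichment

Both tests draw random gene sets **with replacement** from the
expressed universe, exactly as the procedure they reimplement states,
even though a hypergeometric draw would be more conventional. p-values
use the add-one rule p = (k+1)/(n+1), so p is never 0; when no draw is
as extreme, the result additionally carries the "< 1/n_draws"
reporting convention as a flag. Because with-replacement draws make
the TF-frequency null exactly Binomial(bin, f), the exact tail is
computed alongside the MC estimate — the MC estimate is validated
against it to 3 MC standard errors, and the exact tail is the honest
answer when the true p is below the MC floor (a printed p of 9e-8
cannot come from 1e6 raw draws). The pathway statistic is the mean
log2FC of the set; extremeness is two-sided via |null mean| ≥
|observed mean| (the verbal definition upstream is self-contradictory;
the absolute-value reading is the documented choice), with direction
reported as the observed sign. A convergence diagnostic reruns a test
at 10²…10⁶ draws with child seeds and flags stability (< 10% relative
change), mirroring the draw-count escalation protocol.

## Exon–intron split analysis

Each matrix (exonic, intronic) is normalized to CPM against its own
library size, +1 pseudocount, log2, averaged within the pre/post
windows; Δ = post − pre. Genes with fewer than 8 summed reads in
either matrix in either window are excluded (a guard against
log-of-noise for intron-poor genes; not part of the source procedure,
disableable, and the excluded count is reported). The Pearson r over
genes between Δexon and Δintron is the headline statistic and r² the
transcriptional fraction; r is affine-invariant and the recovered r²
is monotone in the generator's coupling parameter.

## ATAC accessibility

Reported log2FC per peak is log2(mean_b + 1) − log2(mean_a + 1) on
per-timepoint mean counts; significance comes from the NB LRT on the
raw replicate counts (count models belong on counts; the +1 log means
are reporting only). Gained/lost require |log2FC| > 1 at BH FDR
< 0.01; all-zero peaks are stable by convention and flagged. The ten
highest-total peaks are removed as outliers, ties broken by genomic
order so the surviving set is order-invariant. TSS distance is
|peak midpoint − nearest TSS| on the same chromosome, strand-agnostic
(midpoint rather than edge: symmetric and standard; the upstream
choice is unstated). CTCF sites are counted at log2-odds ≥
min(10, matrix maximum) on both strands at every offset with overlaps
allowed (simplest well-defined rule; verified against an exhaustive
brute-force scorer). Stratification reports the fraction of peaks
with log2FC < −1 per CTCF group (0/1/2/≥3 sites), a 2-D density over
(log10 distance, log2FC), and a Spearman width-vs-|log2FC| trend.

## Elastic-net motif regression

Objective (glmnet parameterization):
`(1/2n)·RSS + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)`. Predictors (motif hit counts,
width, G+C count, CpG count) are standardized before penalization and
coefficients reported on the original scale; zero-variance columns are
dropped with a warning. scikit-learn's coordinate descent is the
solver (its objective is identical under alpha→λ, l1_ratio→α); fits
are verified against the KKT subgradient conditions to 1e-6
independently of the solver, λ=0 reduces to least squares, and pure
ridge (α=0) uses the closed form. The grid search covers α ∈ 0…1 step
0.1 with a per-α λ path of 100 points log-spaced over 4 decades below
λ_max = max|X'y|/(n·max(α, 1e-3)); folds come from one seeded shuffle
shared across all grid points; the winner is the global CV-MSE
minimum with ties to the larger λ (sparser). Predictors are ranked by
|β|, covariates flagged separately, zero-β predictors omitted. The
response is the P3→P6 accessibility log2FC — the comparison in which
the chromatin actually moves.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical *structure* the analyses
assume, with defaults chosen to match the study conditions:

- 2,000 expressed genes (plus 30% sub-threshold genes forming the low
  abundance mode the threshold scan needs), 13 days × 3 replicates,
  NB counts (gamma–Poisson, dispersion 0.05), lognormal library sizes
  around 2e6.
- 14% switch genes (4.5% on, 9.5% off) with logistic time courses
  centered on day 6, time scale 0.25 days — the transition starts at
  day 5 and is complete by day 7 without a discontinuity. Magnitudes
  are 1 + Exp(1.5) log2 units capped at 10 (2- to ~1000-fold).
  Switch genes peak at their drawn base abundance: on-genes start low
  and rise to it, off-genes start there and fall, as real
  stage-specific genes do. Constant genes are exactly flat; "other"
  genes drift by N(0, 0.3) clipped to ±0.8.
- The pre-switch state is rescaled once so Σ rpkm·length = 1e9,
  keeping measured RPKM on the intended scale for a 2,000-gene panel.
- TF labels: 6% of expressed genes overall, 23% within the 100
  strongest off-switching genes (preferential labeling in the ranked
  tail, then filling to the global rate — infeasible combinations
  raise). Pathways include an on-biased ("phototransduction-like"),
  an off-biased ("axon-guidance-like") and three null sets, plus a
  41-gene cone-specific set drawn mostly from switch-on genes.
- Exon/intron coupling: for transcriptional genes the intronic
  expected count tracks the *realized* exonic count (pre-mRNA moves
  with transcription), for the rest it stays at the pre-switch
  baseline; intron depth is 0.6× exonic with dispersion 0.01
  (conditional on the realized transcriptional state the intron
  measurement is mostly technical). Under this coupling the recovered
  r ≈ √f; the default transcriptional fraction 0.72 was calibrated
  over 10 seeds to yield r ≈ 0.84 (observed 0.830 ± 0.025), and the
  sweep endpoints f = 0, 1 recover r² within 0.03 of 0 and 1.
- ATAC: 5,000 non-overlapping peaks, one per 5 kb cell of a synthetic
  25 Mb chromosome; 20% promoter-like (a TSS within ±250 bp, widths
  ~900 bp) and 80% enhancer-like (distal, ~350 bp). CTCF-like motifs
  are planted at Poisson(1.0) per peak (decoys at Poisson(0.4)), and
  the truth table's CTCF counts are the scanner's own counts on the
  emitted sequence, so generator and scanner agree exactly by
  construction. P(loss P3→P6) = logistic(−4.825 − 1.4·ctcf +
  1.1·log10(distance) − 0.9·width_kb), giving ~27% loss without CTCF
  sites falling below 1% at ≥3 sites, losses ≈ 6× gains (gain
  probability 0.025), and ~0.05% late (P6→P10) changes. Accessibility
  changes are 1.5–3.5 log2 units, NB counts around a lognormal
  baseline of ~60 reads.

All randomness flows from one seed through
`SeedSequence([seed, stage])` spawns, making outputs byte-identical
across runs and platforms.

What the generator does **not** emulate: read-level artifacts
(mappability, GC bias, fragment lengths), gene–gene correlation,
compositional drift beyond the switch itself, overlapping or called
peaks (peak calling is upstream and out of scope), binding-site
degeneracy (planted motifs are consensus instances), and batch
structure. Passing recovery tests therefore demonstrates that the
estimators are correct and calibrated under the assumed generative
model — not that the assumed model captures every property of real
libraries.

## Problem sizes

Tests and the acceptance script run the default study sizes —
2,000 expressed genes × 39 samples and 5,000 peaks × 9 samples — with
reduced replicas (300–1,500 features) where a property does not need
the full size. Permutation tests use 1e5 Monte Carlo draws in checks
(the CLI default is 1e5, configurable to 1e6), with the exact
binomial tail available wherever the with-replacement null applies.

## Known limitations

- The LRT is mildly liberal at 3 replicates per group (the ATAC
  design); the FDR 0.01 + |log2FC| > 1 double gate keeps the realized
  false-call rate far below 1% in the null simulations.
- The moment/shrinkage dispersion estimator is simpler than the
  empirical-Bayes estimators of dedicated packages; it is calibrated
  at the pipeline's sample sizes but not optimal at n = 3.
- The pathway test inherits the with-replacement convention, which is
  slightly conservative for large pathways relative to a
  without-replacement null.
- The elastic-net λ path length and fold assignment are explicit
  choices; a data set's (α, λ) optimum depends on them, so only the
  ranking of predictors — not the scalar optimum — is treated as the
  result.
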