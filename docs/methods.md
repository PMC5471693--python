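# Methods

This note documents the models, estimators and numerical choices behind
`aphidx`, and what the synthetic system does and does not emulate.

## The biological system being modeled

An X0/XX insect: females carry two X chromosomes and two copies of each
autosome; males carry a single X. Absent any correction, an X-linked gene
transcribed at the same per-copy rate in both sexes yields half the output
in males. Dosage compensation is modeled as a per-copy doubling of male X
transcription. The X is additionally *masculinized*: male-biased genes
outnumber female-biased genes 3:1 on the X (even numbers on autosomes), and
biased genes are modeled as essentially sex-specific — transcribed at the
shared base rate in the favored sex and at base/`bias_fold` (default 50) in
the other. This is what produces the diagnostic asymmetry: the female X
carries a cohort of near-silent (male-specific) genes that drags the female
X median down, so the female X/A ratio over all expressed genes sits well
below 1 while the ratio over unbiased genes alone approaches 1.

## Expression pipeline

**Normalization.** Between-library scaling uses TMM: pairwise log2 ratios
(M) against a reference library, genes with a zero in either library
excluded, 30% two-sided trim on M and 5% on A, inverse-asymptotic-variance
weighting, factors rescaled to geometric mean 1. The reference library is
the one whose upper-quartile count fraction is closest to the mean upper
quartile. Unit conversions: CPM = c·10⁶/N_eff, RPKM = CPM/length_kb, TPM =
length-normalized rates renormalized to 10⁶ per library, with N_eff = depth
× TMM factor when TMM is enabled. Gene length is summed exon length; the
config can switch to CDS length where annotations warrant it.

**Gene classes.** *Unexpressed*: CPM < 1 (raw-depth CPM) in at least 3 of
the 6 libraries, applied across morphs exactly as stated; the threshold
count is configurable because a gene expressed in only one morph's three
libraries sits on this boundary by construction. *Biased*: a genewise
conditional exact test. Counts are rescaled to the geometric-mean effective
depth (rounded half-to-even), group sums formed, and under the null of equal
means the two group sums are negative binomial with sizes n₁/φ and n₂/φ;
conditioning on the total, the two-sided p is the probability of all splits
no more probable than the observed one (the "small-p" double tail; it
reduces to a conditional binomial in the φ → 0 Poisson limit). BH step-up
q-values; male/female-biased at q < 0.05 (strict) by the sign of the mean
difference; unexpressed takes precedence.

**Common dispersion.** A single moment-matched φ: on depth-equalized
counts, within-group mean m and variance s² satisfy E[s²] = μ + φμ², and φ
is estimated as the pooled ratio Σ(s² − m) / Σ(m² − s²/n) over genes and
groups, clipped at 0. The denominator's s²/n term removes the upward bias of
m² as an estimate of μ² at 3 replicates; a plain per-gene average of
(s² − m)/m² is strongly biased at this replication level and was rejected.
Recovery on simulated truth: φ̂ ≤ 0.01 under Poisson data and φ̂ within
[0.15, 0.25] for true φ = 0.2 at 5000 genes.

**X/A ratio and sweep.** The ratio statistic is the ratio of medians
(median X expression / median A expression) on the linear scale; medians
pair naturally with the rank-sum comparison and resist the heavy right tail
of expression data (a mean-based variant is available). The Wilcoxon
rank-sum test is exact for untied samples of ≤ 50 per group and a
tie-corrected normal approximation with continuity correction otherwise.
Threshold sweeps filter on the joint male+female mean (`joint_mean`) or on
each morph's own mean (`per_morph`); compensation is called when
0.95 ≤ ratio ≤ 1.05 and p > 0.05. log2(RPKM+1) is used only for
class-stratified summaries, never for the ratio itself.

## Chromatin pipeline

**Signal.** Coverage tracks are 10-bp binned (length-weighted means; the
last partial bin is averaged over its real width). 1× depth normalization
scales a track so the mean bin value over the anchor region is 1. The
default anchor is the genome; for *cross-sex* FAIRE/Control comparisons the
pipeline anchors on autosomal bins only, because in an X0 male the haploid
X halves its share of control DNA and a genome-wide mean would shift the
male's normalization constant by the X genome fraction — an artifact of the
constant, not of accessibility (the same ploidy bias the analysis design
addresses by treating X and autosomes separately). The input-normalized
signal is (FAIRE + ε)/(Control + ε) per bin with ε = 0.5 on both sides
(configurable), which defines 0/0 bins as 1 and stabilizes low-coverage
bins.

**Profiles.** Metagene rows are 50 upstream flank bins, the gene body
resampled to 150 bins, and 50 downstream bins, oriented 5′→3′ (minus-strand
rows reversed). Body resampling is length-weighted bin averaging via the
cumulative sum — it maps constants to constants and conserves the body mean
exactly, unlike interpolation. Flanks are raw bins, never resampled;
windows clipped at scaffold edges become missing values excluded per
column; genes shorter than one bin are flagged and excluded. Summit windows
are 200 raw bins (±1000 bp) centered on the summit's bin, with no strand
flipping (summits are unstranded). Confidence bands: percentile bootstrap
over rows (resample size = row count, 1000 resamples, 99% level by default,
seeded); the reported mean is the plain column mean — bootstrap affects
bounds only. Library similarity is Pearson correlation of per-library
10-bp-bin coverage restricted to the merged union of peak intervals, with
average-linkage clustering on 1 − r.

**Peak features.** The TSS feature is the 200 bp upstream of the first
5′UTR base in transcript orientation; the promoter extends 1300 bp upstream
and is trimmed to [TSS−1300, TSS−200) so features tile disjoint ground
(untrimmed promoters are available — the two conventions differ only in
whether the TSS window is double-labeled). Genes without a 5′UTR anchor
both windows at the gene's 5′ end and are flagged (optionally skipped).
Coding regions are CDS intervals; introns are the gene span minus exons;
intergenic is the exact complement of all gene-derived features. Peak
densities are peaks per Mb of feature length, and a peak credits every
feature it overlaps by ≥ 1 bp. Sex overlap reports per-peak shared counts
in both directions plus the number of merged union regions containing both
sexes (a symmetric quantity, robust to chained overlaps).

## The synthetic generator

The generator inverts the analysis model so parameter recovery is testable.

* **Genome**: one autosomal and one X scaffold (8 Mb each by default),
  1200 + 800 structured genes (5′UTR exon, 2–4 CDS exons with introns,
  3′UTR exon, mixed strands, non-overlapping with random intergenic gaps).
* **Expression**: per-gene base rates come from a deterministic lognormal
  quantile grid per chromosome (mean log2 8, sd 1.5 on the CPM scale),
  randomly matched to gene positions, with class labels stratified across
  the expression-ranked grid. This makes the X and A gene populations
  exchangeable apart from the modeled effects, so the compensated X/A ratio
  is an unbiased ≈ 1 and its remaining Monte-Carlo error comes from NB
  sampling alone (a few percent at 2000 genes); with iid base-rate draws
  the ratio of medians would carry ~±10% gene-population noise at this n,
  drowning the compensation band. Class fractions: A = 30% unexpressed /
  10% male-biased / 10% female-biased; X = 40% / 15% / 5% (the 3:1
  masculinization).
* **Counts**: NB with mean μ + φμ² variance (φ = 0.1), μ proportional to
  lib_size × base rate × exon length × bias × dose; dose is 2 except the
  uncompensated male X (1). A single global constant matches the mean
  library total to the mean configured depth, so library totals still shift
  compositionally with the planted structure (what TMM corrects).
  Unexpressed genes keep μ × 10⁻³ so the CPM < 1 filter is exercised rather
  than trivially passed. Default library depths are 2.5–3.5 M counts.
* **Chromatin**: control fragment midpoints are uniform at a rate
  proportional to copy number; FAIRE adds Gaussian TSS bumps (σ = 100 bp)
  with amplitude growing as log1p of that sex's true expression, plus
  intergenic enrichment sites (40% shared, 30% per sex), and the entire
  male-X FAIRE rate is multiplied by the per-copy accessibility factor
  (default 2 — a modeling choice for the "almost two times higher" scale of
  the effect, not a measured value). Fragments are 200 bp; 2 M FAIRE and
  1 M control fragments per sex by default. Peak calls are emitted at TSSs
  of genes whose expression exceeds 10% of that sex's upper-quartile CPM
  (the quartile anchor keeps the rule independent of gene count) and at the
  sex's intergenic sites.

**What the generator does not emulate**: mappability and GC biases,
chimeric scaffolds, fragment-length variation, overdispersion differences
between genes (the dispersion is common), sexual-female morphs, read-level
artifacts, or genuine uncompensated biology beyond the dose switch. Passing
tests therefore demonstrate that the pipeline recovers the planted
structure under its own model assumptions — not that real libraries are
free of these additional effects.

## Measurement protocols and numerical choices

* The compensation-recovery check measures the X/A ratio and rank-sum p as
  medians over 5 replicate simulations (seeds derived from one master seed)
  and applies the compensation rule to the aggregate: one 2000-gene genome
  carries ≈ 3–4% sd on the ratio of medians from NB sampling, so a
  single-replicate verdict against a ±5% band would be noise-limited while
  the estimator itself is unbiased. The moderate TPM threshold used for the
  readout is 75 on the default simulation's scale (mean TPM = 10⁶ / 2000
  genes = 500).
* Ploidy checks compare the measured control A/X mean-coverage ratio with
  its analytic Monte-Carlo standard error from the fragment counts
  (3 SE acceptance band).
* Exact-test p-values are computed in log space with logsumexp; ties in
  "no more probable than observed" use a 10⁻¹⁰ relative tolerance. TMM and
  the exact test were cross-checked once against an independent reference
  implementation and those values frozen into the suite.
* Degenerate inputs fail loudly: all-zero libraries, negative dispersion,
  empty chromosome classes, zero-variance correlation vectors, intervals
  outside scaffolds, summits outside peak spans.
* Problem sizes in the test suite are scaled (60–200 genes, 10⁵-scale
  fragment counts) except where a check is about the default conditions
  themselves; the acceptance script runs the full default sizes.

## Known limitations

* The common-dispersion exact test is simpler than quantile-adjusted
  conditional likelihood estimation; with 3 vs 3 replicates and a shared φ
  it is slightly conservative (the null false-discovery fraction sits well
  below the nominal level).
* The TSS of a gene without an annotated 5′UTR falls back to the gene span
  end, which misplaces promoter windows where UTRs are genuinely missing
  rather than unannotated.
* bigWig input/output is not supported; coverage exchange is bedGraph.
* TPM is invariant to per-library depth rescaling, so TMM has no effect on
  TPM values (it does affect CPM/RPKM); the flag is accepted uniformly for
  interface consistency.
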