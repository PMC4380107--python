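# Methods

## Scientific setting

Gene promoters carrying 5-hydroxymethylcytosine (5hmC) in normal colon
epithelium behave distinctively in colorectal cancer: although 5hmC itself is
globally depleted in tumours, the promoters it marks tend to resist DNA
hypermethylation and, if anything, lose methylation, while promoters lacking
5hmC — many of them bivalently marked in embryonic stem cells — are the ones
prone to methylation gain. TET2-bound promoters show the same protection.
`hydroxymet` implements the full analysis chain needed to make those
statements quantitative: hmeDIP-seq promoter profiling, Infinium-style
two-channel differential methylation, and the set-level integration
statistics — together with a synthetic cohort generator that plants all of
the relevant structure so every stage can be tested against known truth.

## Coverage and profile quantification

DIP-seq reads arrive as BED intervals. Coverage tracks are binned (default
50 bp), normalised to reads per million mapped (RPM) and the matched input
library is subtracted bin-wise; negative net values are retained because all
downstream consumers rank or average. Coverage uses per-bin overlap counting
(a read spanning k bins increments each) for smooth tracks, while every
count statistic — feature distribution, promoter scores, probe-window
counts — assigns each read exactly once by its midpoint, under half-open
`[lo, hi)` windows. Feature assignment precedence is promoter > gene body >
intergenic, with the promoter defined as the strand-aware TSS −1 kb/+0.5 kb
window and the gene body as TSS..TTS.

Promoters are ranked twice: by midpoint read count in the −1 kb/+0.5 kb
window and by count across the gene body. The top-N of each ranking are the
'narrow' and 'broad' candidates; a promoter appearing in both raw lists is
assigned to the list where its rank is better (tie → narrow), yielding
disjoint unique sets. The de-duplication rule is a declared choice (the
unique-list construction is not otherwise pinned down); plain set difference
is available via `dedup="difference"`. Rank ties break by gene identifier
for reproducibility.

Island/shore meta-profiles length-normalise each CpG island to a fixed
number of meta-bins (default 40) and tile the flanking shores (default
2 kb) in fixed-bp bins, orienting upstream/downstream by the host promoter's
strand. Joint 5hmC/5mC profile clustering z-scores each promoter's
concatenated positional profile and applies k-means (k = 10, k-means++
initialisation, ≤ 300 iterations, fixed seed). K-means is a deliberate,
reproducible stand-in for interactive heatmap clustering tools; it is not
expected to reproduce any particular published cluster boundaries.

## Sequence annotation

CpG islands are called with the Gardiner-Garden criteria: every 200 bp
window (step 1) with GC ≥ 0.50 and CpG observed/expected ≥ 0.60 is marked
and overlapping windows are merged into maximal islands, where
obs/exp = (#CpG · L)/(#C · #G) and a zero C or G count defines obs/exp = 0.
Promoter CpG-content classes use the standard three-class windowed rule on
the TSS −1300/+500 bp context with 500 bp windows at 5 bp offsets: HCP if
any window has GC ≥ 0.55 and obs/exp ≥ 0.75; LCP if no window reaches
obs/exp ≥ 0.48; ICP otherwise. Array probes are assigned to the gene with
the smallest strand-aware |distance to TSS|, up to 1,499 bp inclusive
(1,500 bp is unassigned); ties break lexicographically.

All internal coordinates are 0-based half-open; manifest positions are
1-based on disk and converted on I/O.

## Array processing

Beta values are M/(U + M) with no offset; records with M + U = 0 are
missing. Probe filtering drops records with detection p ≥ 0.05 (strict) and
removes cross-reactive, SNP-containing and sex-chromosome probes entirely.

Differential methylation is modelled on the stabilised channel log-ratio
log2((M + a)/(U + a)), a = 100 by default (0 disables). Assuming channel
variance proportional to intensity (var X = X/φ with dispersion φ), the
delta method gives var(log2 X) ≈ 1/(X φ ln²2), summed over channels; the
reciprocal squared standard errors are the regression weights. Per probe,
paired tumour−normal differences are combined by weighted least squares and
the residual variances are moderated by empirical Bayes: the prior
(d₀, s₀²) is fitted by matching the mean and variance of log s² to the
digamma/trigamma moments of the log scaled-F distribution (the raw moments
of s² only exist for d₀ > 4, so log-moment matching is used), and the
posterior variance is s̃² = (d₀s₀² + d·s²)/(d₀ + d) on d₀ + d degrees of
freedom. Probes are labelled gain/loss by the sign of the mean paired beta
difference when the two-sided moderated-t p is below α = 0.01, with no
magnitude floor; Benjamini-Hochberg adjustment is deliberately not applied
by default. A probe-level stratum column (e.g. colour channel), when
supplied, splits the analysis into independently moderated strata.

The type I/II design bias is corrected by peak-based rescaling: per sample,
betas of each design type are mapped to M-values, the unmethylated (M < 0)
and methylated (M > 0) density peaks are located by Gaussian KDE (Silverman
bandwidth, argmax on a fixed grid), and type II M-values are rescaled by
separate positive factors on each branch so its peaks land on type I's,
then mapped back to beta. Type I probes pass through bit-identical; the map
is piecewise linear through 0 on the M scale, hence monotone. If either
type lacks a detectable peak on one side of 0 the sample is passed through
with a warning.

Rank tests: the gene-set test is the mean-rank (Wilcoxon rank-sum
equivalent) test of a probe set against its complement — exact by subset
enumeration when both sides have ≤ 10 members, otherwise a tie-corrected
normal approximation with continuity correction. The two-sample comparison
uses the same machinery with exact enumeration up to a pooled size of 12.

## Integration statistics

The 5hmC-high set is the top-N array loci by mean RPM-scaled read count in
200 bp probe-centred windows across the normal DIP libraries (per-sample
RPM then averaged — the pooling rule is config-switchable to raw pooling);
the 5hmC-low set is the bottom-N including zeros. Cross-tabs report the
gain/loss split of significantly changed probes inside each set.

TET2 target promoters are those whose TSS ± 1 kb window overlaps a peak by
≥ 1 bp. Overlap depletion between the methylation-gain promoter set A and
the TET2 set B over a universe of n promoters is tested with a binomial
null — each of A's members lands in B with probability |B|/n — reporting
P(Bin(|A|, |B|/n) ≤ observed) for depletion and the complementary tail for
enrichment; a hypergeometric (without-replacement) variant is available
since the sampling model is a genuine modelling choice. Promoter-level
bookkeeping aggregates probes by nearest-TSS assignment; any significant
probe confers its label on the promoter.

The bivalency analysis is a three-way Venn over a shared promoter universe
(5hmC-marked, bivalent, methylation-gain), reporting all seven region
counts plus the two headline fractions |gain ∩ bivalent|/|gain| and
|5hmC ∩ bivalent|/|5hmC|. The hmC-contamination estimate is
pct_hmC/(pct_hmC + pct_mC): bisulfite-based assays read 5hmC as 5mC, so
this is the share of apparent methylation attributable to 5hmC. The global
modification percentages are inputs (mass-spectrometry-style medians); the
pipeline config carries illustrative defaults (0.118/4.8 normal,
0.031/4.4 tumour, % of cytosines) of the magnitude such measurements give
in colon tissue. Persistent-5hmC promoters are those whose tumour
probe-window signal stays at or above a detection floor (default 1 RPM,
itself a declared choice); gain/loss fractions over that set use the set
size as denominator.

## Synthetic cohort generator

The generator emulates the structure of a matched-cohort study with 17
normal/tumour array pairs and 5 + 5 DIP libraries, on a compact genome (1
chromosome × 5 Mb, 300 genes by default, ~1/3 narrow, 1/3 broad, 1/3
unmarked promoters).

* **Genome.** Background sequence is drawn i.i.d. at GC 0.38 and CpGs are
  then suppressed (each CpG's G mutated to A with probability 0.9, which can
  never create a new CpG) — a two-regime dinucleotide sampler. Promoter
  island segments (TSS −400/+600) are planted per class: broad promoters
  get strong islands (GC 0.65, no suppression → HCP), narrow promoters weak
  islands (GC 0.50, suppression 0.45 → ICP), unmarked promoters none
  (→ LCP), mirroring the observed association of broad profiles with
  high-CpG promoters and narrow profiles with intermediate-CpG promoters.
  Genes are placed non-overlapping on both strands with recorded TSS/TTS.
* **Reads.** Fixed-length intervals (36 bp; fragment-length modelling is
  deliberately omitted since all statistics count reads). Each IP read is
  background (uniform) or enrichment with weight 0.7; narrow promoters use
  two Gaussian flanks (centres −600/+250, sd 120, upstream weight 0.6)
  truncated to −1 kb/+0.5 kb with the ±100 bp TSS bin excluded (the
  characteristic TSS dip); broad promoters use a uniform gene-body
  component. Tumour libraries multiply the enrichment weight by the global
  depletion factor 0.3, the displaced mass becoming background — what a
  less specific pull-down yields. Input libraries are background-only.
* **Arrays.** Two probes per gene at offsets in [−800, +400]. A probe's
  local 5hmC truth ("high"/"low") is computed analytically as the expected
  share of the host promoter's enrichment reads falling in its 200 bp
  window; this matters because probes in unenriched spots of marked
  promoters (the TSS dip, upstream of broad gene bodies) are measured as
  5hmC-low, and the planted reciprocal pattern is defined per locus.
  Normal-state betas are intermediate at 5hmC-high loci (N(0.45, 0.12),
  truncated) and low at 5hmC-low loci (N(0.12, 0.07)); these parameters are
  not published anywhere and are config-exposed. Changes are planted per
  probe: gain 0.04 / loss 0.16 at high loci (4:1 loss-dominant) and gain
  0.13 / loss 0.10 at low loci (1.3:1 gain-dominant), shifting the tumour
  beta by ±0.25 with clipping to [0.01, 0.99]. Per-sample noise is a
  clipped Gaussian on the beta scale (sd 0.03) — simple, bounded and
  sufficient for planted-effect recovery. Type II betas are compressed
  toward 0.5 by factor 0.8 before intensity synthesis; channel intensities
  are float-valued with M + U equal to a drawn per-record total
  (mean 2,000, CV 0.1), so a noiseless configuration round-trips betas
  exactly. Detection failures are independent per record at rate 0.005;
  2% each of probes carry cross-reactive/SNP flags and 2% of
  first-chromosome probes are labelled sex-chromosomal (no actual X/Y
  sequence is generated).
* **Peaks and bivalents.** TET2-like promoters (30% of genes) are drawn
  preferentially from island promoters without planted gain (strong islands
  first) and receive one peak each inside TSS ± 1 kb — the planted
  exclusion that the depletion test must detect. Bivalent flags are
  assigned so that exactly round(0.65·n) of gain-prone promoters and
  round(0.30·n) of 5hmC-marked promoters are bivalent.

Every stochastic choice flows from a single seed through spawned
generators; a fixed config yields byte-identical output files.

### What the generator does not emulate

No sequencing errors, duplicate reads, mappability structure, copy-number
variation, batch effects, cell-type composition, probe cross-hybridisation
signal (only the flag), or genuinely positional 5mC profiles (the pipeline's
joint clustering uses a constant-per-promoter methylation track derived
from normal betas, since meDIP-style 5mC reads are not generated). Passing
tests therefore demonstrate that the implementations compute their
statistics correctly and recover planted structure at realistic effect
sizes and depths — not that the pipeline is robust to every artefact of
real sequencing and array data.

## Numerical choices

* KDE peak location uses a fixed grid of 4,001 points over M ∈ [−8, 8];
  grid resolution bounds the correction's accuracy at ~0.004 M-value units.
* Rank ties break by identifier everywhere (promoter ranking, locus
  selection) so that outputs are total orders.
* The moderated-t reduces exactly to the ordinary paired t when the prior
  degrees of freedom are forced to 0 and weights are equal; when the
  observed spread of log s² is no larger than chi-square sampling predicts,
  d₀ = ∞ and the test becomes a z-test against the pooled variance.
* Empty or degenerate inputs raise errors rather than returning silent
  defaults (zero mapped reads, empty read sets, locus sets exceeding the
  probe universe, gene sets equal to their universe).

## Problem sizes

The default synthetic cohort (5 Mb, 300 genes, 200k reads/library, 600
probes × 34 samples) runs the full pipeline in a few seconds; locus-set
sizes are scaled accordingly (top-150 high/low loci, top-100 profile
lists). The reciprocal-pattern experiment uses a larger cohort (20 Mb,
1,500 genes, 6,000 probes, top-1,500 sets, 20 seeded replicates) because
detecting a 1.3:1 asymmetry reliably needs set sizes in the thousands, as
in the full-scale design. The full-scale defaults (top-3,000 loci,
1,499 bp probe assignment, α = 0.01, k = 10) remain the `PipelineConfig`
defaults; `PipelineConfig.desk_scale()` sizes the lists for the synthetic
cohort.

## Known limitations

The narrow/broad lists, locus sets and cluster assignments depend on rank
cutoffs, not significance thresholds; cohort-scale published list sizes are
descriptive, not targets. The binomial depletion null treats promoters as
exchangeable; promoter-level covariates (CpG class, expression) are not
adjusted for. Channel-level dye bias beyond the peak-based correction, idat
parsing and cell-composition deconvolution are out of scope.
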