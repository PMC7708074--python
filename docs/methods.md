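# Methods

This note documents the models behind `cracmap`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical conventions that make results bit-reproducible.

## Coordinate model

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
inclusive) is converted at the I/O boundary, BED/bedGraph are native.
A transcript's *mature* axis is the spliced 5′→3′ coordinate system;
for mRNAs it is partitioned into contiguous 5′UTR / CDS / 3′UTR blocks
whose lengths are taken from UTR features when the annotation provides
them and otherwise derived from the CDS extent. Intron-containing
transcripts are supported through exon chains; mature coordinates are
spliced. mRNAs with an empty 5′ or 3′UTR load normally but are flagged and
excluded from metagene/region-fraction outputs (rescaling an empty region
into a fixed bin count is undefined); exclusions are reported in a skip
list so they are never silent.

## Read assignment

CRAC reads are short and crosslink-proximal, so each read is reduced to a
single point — its midpoint `⌊(s+e−1)/2⌋` — and assigned once. The rules
are chosen to be deterministic and order-free:

* **class**: midpoint containment, with a fixed priority
  rRNA > tRNA > snRNA > snoRNA > mRNA > other (configurable). The order
  mimics abundant-RNA masking in crosslinking pipelines: a read inside
  both an rRNA and an mRNA annotation is almost surely ribosomal.
* **transcript**: same-strand midpoint containment; among several
  containing transcripts the largest total exonic overlap with the read
  wins, remaining ties go to the lexicographically smallest id.
* **region**: the mature position of the midpoint, classified by the
  half-open 5′UTR/CDS/3′UTR boundaries.

Only uniquely mapped reads are counted (BED score 1, or SAM MAPQ ≥ 1).
RPM uses the number of transcriptome-assigned unique reads in the sample
as denominator by default — downstream thresholds are defined on
transcriptome-mapped signal — but any denominator (e.g. all genome-mapped
reads) can be supplied to `rpm_normalize`.

## Metagene

Bins: 10 / 100 / 10 for 5′UTR / CDS / 3′UTR (configurable). Within a
region of length L and n bins, offset d maps to `min(⌊d·n/L⌋, n−1)`; the
final clamp absorbs the short tail when L is not a multiple of n. Each
transcript's histogram is normalized to unit sum before averaging; the
aggregate is therefore the arithmetic mean of per-transcript distributions
rather than a pooled read histogram. The mean was chosen because pooling
re-introduces the abundance weighting the per-transcript normalization is
meant to remove; the choice matters only when profiles vary with
abundance.

The aggregate filter keeps transcripts with pooled tagged signal above
`min_rpm` (default 100 RPM). A raw-read-count variant
(`filter_mode="reads"`) is provided because the two readings differ when
library sizes stray from 10⁶.

Boxplot summaries use linear-interpolation percentiles (numpy default) and
Tukey whiskers: the most extreme data points within 1.5·IQR of the
quartiles; values beyond are listed as outliers. The percentile convention
is stated because quartile definitions differ across software and the
summary is meant to be bit-reproducible.

## Replicate statistics

Correlations and PCA act on log₂(RPM + 1) over transcripts detected
(nonzero) in at least one sample. The pseudocount of 1 RPM keeps zeros
finite and stabilizes the heavy right tail; the transcript filter is
configurable (`"all"` keeps everything). Spearman is Pearson on mid-ranks.
PCA centers features (transcripts) without unit-variance scaling — all
features share the log-RPM scale — and takes components from the SVD of
the centered samples × transcripts matrix. Component signs are fixed by
making the largest-magnitude transcript loading positive, so coordinates
are deterministic. Variance explained per component is the squared
singular value over their total; with k samples there are k−1 informative
components and the percentages sum to 100.

## Target calling

A high-confidence target passes all three filters with *strict*
inequalities: mean tagged CRAC RPM > 128, CRAC/RNA-seq ratio of mean RPMs
> 1.5, and one-sided enrichment p < 0.01. When the RNA-seq mean is zero
the ratio is flagged infinite and the ratio filter defers to the RPM
filter. Raw p-values drive the filter; Benjamini–Hochberg q-values are
emitted for information only, since the three-filter convention reports
raw p.

### Enrichment test

Two tests are implemented on log₂(RPM + 0.5):

* `welch`: a one-sided Welch t-test treating all tagged libraries
  (including technical replicates) as independent samples. Degenerate
  inputs — both groups with zero variance — return p = 1 for equal or
  lower CRAC means and the smallest positive float (flagged by magnitude)
  when CRAC is higher.
* `moderated` (default): technical replicates share their biological
  replicate's noise, so they are first averaged within biological
  replicates; treating them as independent understates the standard error
  and inflates the false-positive rate. With only two biological
  replicates the per-transcript variance estimate has one degree of
  freedom, so each group's variances are shrunk toward a mean-expression
  trend (running median across transcripts, rescaled by the χ² median so
  it is unbiased for the underlying level) with an empirical-Bayes
  scaled-inverse-χ² prior whose degrees of freedom d₀ are fitted by
  moment-matching the spread of log(s²/trend) against the trigamma
  sampling value — the standard small-replicate remedy in sequencing
  statistics. The one-sided statistic uses the moderated variances and a
  Welch–Satterthwaite df with d₀-augmented group dfs.

The mean-expression trend matters because counting noise makes the
log-scale variance depend strongly on abundance; a single pooled variance
would be anti-conservative for weakly covered transcripts. The pseudocount
0.5 (configurable) keeps zero counts finite while distorting the log-ratio
less than a full unit.

### Coverage tracks

Single-locus tracks report raw per-base depth of uniquely mapped reads
(each read contributes 1 across its interval), written as bedGraph runs;
for a transcript locus only same-strand reads over its genomic span
contribute. The track maximum is the number a genome-browser scale bar
would display.

## Synthetic data

The generator emulates the statistical structure of a CRAC experiment on
an abundant, 3′UTR-preferring mRNA-binding protein:

| parameter | default | meaning / rationale |
|---|---|---|
| `n_mrna` | 2000 | desk-scale transcriptome; enough mRNAs for stable medians and calibration checks |
| `n_ncrna` | 6 rRNA, 60 tRNA, 6 snRNA, 40 snoRNA, 20 other | a scaled-down non-coding complement |
| UTR/CDS lengths | 5′UTR 30–250, CDS 300–2400 (codon-rounded), 3′UTR 60–400 nt, uniform | yeast-like region sizes; every mRNA has nonzero UTRs |
| `abundance_sdlog` | 1.0 | log-normal expression spanning ~2 orders of magnitude |
| `class_read_shares` | mRNA 0.60, rRNA 0.25, tRNA 0.05, snoRNA 0.04, snRNA 0.02, other 0.04 | tagged-library composition dominated by mRNA and rRNA |
| `region_weights` | (0.05, 0.20, 0.75) | crosslink placement within bound mRNAs: the 3′UTR bias the analysis should recover |
| `propensity_sdlog` | 0.5 | per-mRNA binding propensity spread; creates real protein-specific signal on top of abundance, driving CRAC-vs-RNA-seq rank correlation to ~0.8 and the separation of CRAC libraries in PCA |
| `n_true_targets`, `target_enrichment` | 160, uniform 2.5–4× | spiked true targets, drawn from the upper half of mRNA abundance (real targets of an abundant regulator are well expressed, and this keeps the spike measurable above the RPM filter) |
| `replicate_noise_sd` | 0.49 (natural-log sd) | biological per-transcript noise, shared by a replicate's technical libraries |
| `technical_noise_sd` | 0.10 | residual library-level noise between technical replicates |
| `control_background` | 0.30 | fraction of untagged-control reads scattered uniformly over the genome |
| `reads_per_sample` | 10⁶ | library depth |
| `read_length` | 30 nt | short post-trimming crosslink fragments |
| `te_sdlog` | 0.35 | translation-efficiency spread separating Ribo-seq from RNA-seq |

Replicate-noise calibration: the target for the generator is a
between-biological-replicate rank correlation near 0.8. With abundance
sdlog 1.0 and propensity sdlog 0.5 the cross-transcript signal variance is
s² = 1.25 (natural log); a Spearman of 0.82 corresponds to a log-scale
Pearson of ≈ 0.835 for bivariate normal data, and solving
s²/(s² + σ_b² + σ_t²) = 0.835 with σ_t = 0.10 gives σ_b ≈ 0.49. The value
was fixed analytically from this budget, not fitted to outcomes.

Non-coding abundances are rescaled so each class's abundance share equals
its read share — i.e., by default the protein has no class-level
preference beyond abundance, which keeps CRAC and RNA-seq libraries
compositionally comparable and the enrichment ratio centered at 1 for
non-targets. Reads are placed by sampling a class, a transcript
(∝ abundance × propensity × enrichment × replicate noise), a region
(mRNA only) and a uniform position within the region; the control ignores
propensity, enrichment and noise and adds the uniform background.
Quantitative assays are multinomial draws over all transcripts
(∝ abundance, × TE factor for Ribo-seq); their replicates differ only by
the multinomial draw.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: sequence-dependent crosslinking and UV
photoreactivity biases, PCR duplicates and sequencing error, reads
spanning exon junctions (all simulated transcripts are single-exon;
spliced-coordinate handling is exercised by the annotation tests),
overlapping genes and antisense transcription, multi-mapping ambiguity,
batch effects between the CRAC and the public RNA-seq/Ribo-seq
comparators, and any cell-physiological coupling between binding and
expression. Recovery results on synthetic data bound what the method can
do when its generative assumptions hold; they do not certify performance
on a real library.

### What the recovery experiments can and cannot show

Two experiment designs deserve explicit caveats.

*Spike recovery* measures precision/recall of the target caller against
the spiked set, so its configuration turns the propensity spread off:
with it on, a few percent of non-spiked mRNAs carry propensity factors
above 2.5× — genuinely enriched binders that a correct test rightly calls,
which would corrupt "precision" as a measure.

*Recall is noise-limited by design.* With two biological replicates and
replicate noise calibrated to the ~0.8 replicate correlation, the standard
error of the between-group mean difference is ≈ 0.5 log₂ units; even a
z-test with known variances then detects a 2.5× spike at p < 0.01 only
about half the time. Recall of the 2.5–4× spike therefore sits near 0.5 at
these conditions for any calibrated test — the moderated test tracks that
ceiling — and rises only if replicate noise shrinks (which would push the
replicate correlation toward 0.95) or replication increases. This is a
property of the study design being emulated, not of the implementation;
precision and null calibration are the informative checks at this noise
level.

## Numerical conventions and edge cases

* Integer bin arithmetic (`d·n//L`) avoids float boundary errors.
* All simulation randomness flows through `numpy` Generators seeded from
  the config seed plus fixed stream labels per role/replicate, so samples
  are independently reproducible and byte-identical across runs.
* Read tables are plain pandas DataFrames; interval queries use pyranges
  (NCLS) joins, with ties resolved by explicit stable sorts.
* Zero library sizes, empty profiles, empty boxplots, non-mRNA region
  queries and out-of-range mature positions raise typed errors rather
  than propagating NaN.
* `reduce_redundancy` scans in input order and keeps a sequence iff its
  identity to every kept sequence is below the threshold; identity counts
  identical pairs over all alignment columns, with gap columns counting
  against identity (the convention is stated because published percent
  identities rarely specify their denominator).
* The `+` class in consensus motifs is {K, R} by default; histidine is
  only marginally protonated at physiological pH and can be included via
  `plus_includes_histidine`.

## Known limitations

* The R3H-SUZ conservation comparison against human R3HDM2 requires the
  two real protein sequences (by accession); they are not bundled, and the
  published identity/similarity figures depend on an alignment protocol
  that is not fully specified, so with default parameters (BLOSUM62,
  gap open 10 / extend 0.5) the comparison should be read as approximate.
* No peak calling within transcripts, no crosslink-site (deletion-based)
  inference, no motif discovery at binding sites, and no paired-end logic.
* The enrichment test assumes log-scale noise that is roughly normal
  within groups; heavy-tailed contamination (e.g. mapping artifacts at
  repeat loci) should be filtered upstream.
* `classify_reads` is strand-aware; for unstranded legacy libraries the
  class shares will undercount antisense overlap.
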