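# Methods

This note documents the models, parameter choices, and numerical decisions
behind the package, and what the synthetic-data tests do and do not show
about real data.

## Coordinate and strand conventions

All internal coordinates are 0-based half-open; GTF (1-based inclusive) and
SAM records are converted at the I/O boundary only. The polymerase 3′-end
position of a pair is the first aligned base of read 2 in sequencing order
(`r2_start` on a '+' mapping, `r2_end − 1` on a '−' mapping). Soft-clipped
bases consume no reference coordinate, so stripping clips never moves this
anchor; the clip fields are zeroed and the pair flagged as handled. In the
library design modeled here, read 2 begins at the RNA 3′ end and reads
inward, so it maps antisense to the nascent RNA; the reported strand is the
opposite of the read-2 mapping strand by default, with
`rna_strand_from_read2="same"` available for the other orientation.

## Deduplication

Exact-key collapse on (chromosome, read-2 strand, both mate 5′ positions,
UMI), keeping the first pair encountered. No mismatch-tolerant UMI network
(as in directional collapsing) is applied: exact mode is deterministic and
makes the unique-molecule count a testable quantity. With 8-bp UMIs and
positional keys, distinct molecules colliding on a full key are rare but
possible; the simulator's ground truth therefore counts distinct keys, which
is precisely what a correct deduplicator retains.

## Pause detection

Candidates are positions with count ≥ `min_intensity` (default 5) within
the first `search_region` (default 200) transcribed bases. The null for a
candidate is uniform-multinomial: the total *T* of the `window` (default
100 bp) centered on the candidate and clipped to the search region is
dropped i.i.d. uniformly over the window's *W* positions; the test statistic
of each of `n_bootstraps` (default 10,000) resamples is its maximum
single-position count. The add-one p-value (1 + *k*)/(n + 1) cannot reach
the default threshold of 1e-5 with 10,000 resamples (floor ≈ 1e-4), so when
*k* = 0 an exact Bonferroni/binomial upper bound on the multinomial-maximum
tail, min(1, *W*·P(Binom(*T*, 1/*W*) ≥ *c*)), is reported instead. The bound
dominates the exact tail, so emitted sites are conservative with respect to
the exact null; the bootstrap tail itself is verified against full
enumeration of the multinomial distribution for small (*T*, *W*). Null
resamples are seeded from (seed, *T*, *W*), making calls independent of
candidate evaluation order and bit-reproducible. Multiple sites per gene are
reduced to the highest count, ties broken toward the TSS (the
biologically conservative choice). Whether "highest peak" should mean
highest count or smallest p was an open choice; count was chosen because the
p-value saturates at the analytic bound for all strong sites.

## Pausing indices

The pause-anchored index is the density ratio of [TSS, pause] to the
`body_length` bases downstream of the pause. The default body window is
1000 bp, with the parameter exposed because a 2-kb body is equally
defensible; densities (counts/bp) rather than raw ratios are used so that
variable-length pause regions are comparable across genes, with
`raw_ratio=True` available. The body is truncated at the TES with a flag
when the gene ends first; genes with zero body (or zero pause) signal are
flagged and excluded from ECDFs. The fixed-window index uses
[TSS − 50, TSS + 200) against the remaining gene body, clamped at contig
start. KS comparison computes D exactly on the pooled sample points and the
p-value from the asymptotic Kolmogorov distribution at effective size
n₁n₂/(n₁+n₂); exact small-sample p-values are out of scope.

## Normalization

Median-of-ratios size factors: the reference is the per-feature geometric
mean across samples over features with all-positive counts; a sample's
factor is the median ratio to the reference. Counting is restricted to
regions of interest (e.g. merged TSS+200 windows) because libraries of this
type differ grossly in contaminant content, making total-depth scaling
meaningless.

## Metagene profiles

Rows are genes; columns are 1-bp bins, 200 bp upstream to 1000 bp
downstream of the TSS (reference-point mode) or a linearly rescaled gene
body (scale mode). Genes shorter than the downstream extent are zero-padded
beyond the TES and flagged. "Top and bottom 0.1% outliers" are interpreted
as ranking rows by total signal — the ranking statistic was not otherwise
determined — and ⌈0.001·N⌉ rows are removed per tail. Values become
log2(x + 1); the summary is the per-column mean with a percentile bootstrap
(10,000 row resamples, implemented as multinomial row weights for speed).
Percentile rather than BCa because nothing more specific is required of the
band. The log transform can be disabled (`log_transform=False`) for data on
an unbounded scale.

## Nucleosome dyads

Subnucleosomal fragments are filtered to 58 ± 5 bp, the footprint of one
half of a partially unwrapped histone dyad; midpoints therefore form two
modes ±29 bp around the nucleosome center. Centers are called by Gaussian
smoothing of the midpoint histogram (σ = 15 bp), keeping local maxima with
≥ 10 raw midpoints within ±15 bp as half-peaks, and pairing half-peaks
40–80 bp apart (center = rounded mean; an unpaired half-peak yields a call
with one zero mass). This procedure is this package's own; the upstream
literature's caller is not specified to this level. A −1 nucleosome is any
call whose canonical 147-bp footprint contains an annotated TSS; its dyad
halves are then oriented proximal/distal to that TSS. Pause–nucleosome
distance is strand-aware (positive = pause downstream of the center) and
binned into the five clusters 80–120, 60–79, 40–59, 20–39 and 0–19 bp;
distances outside [0, 120] are unassigned.

In the generator, the dyad-half weights are proximal : distal =
1 : (1 − dyad_loss), so dyad_loss = 0 gives equal masses and dyad_loss = 1
a single proximal mode, and the called distal/proximal mass ratio estimates
1 − dyad_loss directly.

## Concordance and circadian quantification

Per-gene pause anchors are merged across conditions (larger count wins,
ties toward the TSS) and each gene is classified in both the pause region
and a 1000-bp elongation region by a symmetric fold-change threshold
(default 2×) on size-factor-normalized counts, with genes failing a
10-count minimum in either region excluded. The threshold and minimum are
reported with the grid because the three-way fractions
(concordant / single-discordant / double-discordant) depend directly on
them; no published criterion pins these two numbers down, so the package's
grid fractions are not expected to match any particular published split.

Circadian quantification sums exon-only signal (intron positions contribute
nothing, avoiding nascent-splicing artifacts) per gene per timepoint,
normalizes columns by median-of-ratios factors, then row-normalizes to the
peak timepoint for phase readout. Peak/trough amplitude is flagged infinite
when the trough is zero. Genome-wide rhythmicity testing (JTK-style) is
deliberately out of scope.

## Synthetic data

The generator emulates the statistical structure the analyses assume: genes
with ≥ 2 kb intergenic spacing on synthetic chromosomes, one pause site per
gene 20–120 bp downstream of the TSS receiving a configurable fraction
(default 0.3) of the gene's molecules, uniform elongation signal over the
rest of the body, log-normal expression weights, 8-bp UMIs, PCR duplicates
as exact copies (1 + Poisson(1) per molecule), ~40% small-RNA and ~5% rRNA
contaminant molecules (matching the contaminant load typical of 3′-end
libraries without exonuclease depletion), a G(−1)/T(+1) dinucleotide planted
at pause sites, −1 nucleosome centers at the TSS, six-timepoint sinusoidal
transcription with peak ZT14/trough ZT2 and amplitude 0.9, and a
constitutive-pause gene flag that holds pause signal flat while the body
cycles. Where no quantitative value was published (pause strength
distribution, expression spread, fragment lengths), defaults are fixed once
at field-typical values and documented in `SimConfig`.

What passing tests show: coordinate arithmetic, dedup semantics, the
bootstrap null, index/KS/size-factor/metagene computations and the
recovery behavior of each caller are correct under the generative model.
What they do not show: robustness to alignment artifacts, sequencing error
in UMIs, template-switching chimeras, non-uniform elongation (pausing
zones), overlapping gene dense annotation, or mappability gaps — none of
which the generator models.

## Problem sizes

The test suite and the acceptance script run the pipeline at 200–300 genes
and 10⁴–10⁵ molecules per experiment, with 10⁴ bootstrap resamples
(10⁵ where the null is compared against exact enumeration). These sizes
give the recovery and calibration statistics comfortable margins while
keeping a full run in tens of seconds on one CPU.
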