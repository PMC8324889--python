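# Methods

This note documents the models and procedures `milseq` implements, the
defaults it ships with, and what the synthetic-data generator does and does
not emulate.

## Coordinates, coverage, and quantification

All intervals are 0-based, half-open (BED convention) on named chromosomes
with strand `+`, `-` or unstranded; any 1-based dialects are converted at
the I/O boundary. Coverage is held piecewise-constant per chromosome and
strand; a query returns the sum of per-base values over an interval, which
is exact because the representation is exact. Each track carries a library
size supplied by the caller — total mapped reads generally exceed the reads
present in a track, so the library size is never inferred from it.

FPKM of a feature is `reads / (length_kb x library_size_millions)`, with
reads counted by any-overlap on the feature's strand (both strands for
unstranded features). An optional per-feature mappability weight
`m in (0, 1]` divides the FPKM; weights default to 1 (no adjustment) and
are user-supplied, since no general mappability model is assumed.

Two ratio statistics are built on FPKM with a pseudo-count `pc` (default
1.0, configurable):

- methylation level = `(MINT FPKM + pc) / (TT FPKM + pc)`
- relative stability = `(RNA FPKM + pc) / (TT FPKM + pc)`

The pseudo-count bounds the ratio for weakly covered features; it is applied
on the FPKM scale, which is what the defining ratio uses. As `pc -> 0` the
statistic converges to the raw FPKM ratio for expressed features.

## Dual spike-in QC and calibration

Two spike-in sets enter each MINT/TT library pair. Twenty in-vitro
transcripts form five groups of four species, mixed
non-methylated:methylated at 1:0, 3:1, 1:1, 1:3 and 0:1 — designed
methylation levels 0, 25, 50, 75 and 100%. Ninety-two ERCC-like species are
added identically to both libraries, so their MINT:TT relation is a pure
scale: the normalization factor `f` is the zero-intercept least-squares
slope `sum(x*y)/sum(x^2)` of IP reads on input reads across ERCC species.
The zero intercept is deliberate — a ratio of two library scalings has no
offset. The observed level of a spike species is `(IP/input)/f`; the
group-level ratio `r_g` is the mean of per-species ratios by default
(robust to unequal species abundances; a pooled-count mode exists).

The QC statistic is Spearman's rank correlation between observed group
ratios and designed levels. On top of the QC, a linear calibration anchored
at the 0% and 100% groups converts ratios into estimated percent
methylation, `100 (r_g - r_0) / (r_100 - r_0)`. The calibration is exactly
affine-invariant in the observed ratios (so `f` cancels from the estimates;
it is still reported as a QC quantity), the anchor groups map to exactly 0
and 100, and under the generator's capture model the estimator is unbiased:
with per-molecule IP capture probability
`p_g = frac_g * capture_p + (1 - frac_g) * background_p`, the calibrated
estimate has expectation `100 * frac_g` for every group. Absent a dynamic
range (`r_100 <= r_0`) calibration refuses rather than extrapolating.

## Window peak calling

The caller is a deliberately simple substitute for a full MACS-style model,
kept because its statistics are fully auditable: sliding windows (100 nt,
step 50) per strand; per window a one-sided Poisson upper-tail p-value of
the rounded IP count against `lambda = input count x (IP library / input
library)`. The input count is also estimated over a 1 kb window centred on
the test window and the larger of the two estimates is used — per-window
input counts are themselves Poisson-noisy, and treating them as known
inflates false positives several-fold; taking the max is conservative and
also suppresses artifacts at coverage edges. `lambda` is floored at 1
expected count to avoid zero-lambda degeneracy. BH correction runs across
all windows of a strand; windows with q <= 0.01 merge when separated by at
most 100 nt, merged peaks shorter than 100 nt are dropped, and a peak's
fold enrichment is total observed over total expected. Peaks inherit their
track's strand. Externally produced peak BEDs can be substituted anywhere
peaks are consumed; genome-scale peak counts from a full caller are not
expected to be reproduced by this window test.

The expected peak-class distribution assumes any transcribed region is
equally likely to hold a peak: `expected_c = N_peaks x (TT reads in class c
/ total TT reads across classes)`, with overlapping classes resolved by a
caller-supplied priority order.

## MILs and Super-MILs

A MIL is an intronic L1 that is transcribed (TT FPKM > 0.1), longer than
200 bp, fully contained in an intron of at least one gene model, and
overlaps at least one m6A peak on its own strand (>= 1 bp; a minimum
overlap is configurable). L1s passing every filter except peak overlap are
Control L1s. Records are emitted per (L1, host gene) pair because the TBI
and host-gene analyses are gene-relative; a gene counts as a Control-L1
host only if it hosts a Control L1 and no MIL.

Super-MILs use the super-enhancer ranking strategy: sort MIL methylation
levels ascending, min-max scale rank and level to [0, 1], smooth the
discrete slope by central differences over a 5-rank window, and cut at the
index whose slope is closest to 1, breaking ties toward the highest rank.
Elements strictly above the cutoff point — higher rank with level strictly
greater than the cutoff's — are Super-MILs, which makes the Super set a
suffix of the ranking, leaves a perfectly linear ramp with an empty Super
set, and isolates a single high outlier even when the smoothing window
spans the jump. A constant curve yields an empty Super set.

Orientation bias is a two-sided Fisher's exact test of the 2x2 table
[MIL sense, MIL antisense; non-MIL sense, non-MIL antisense] against all
intronic L1s, with expected counts from the background sense fraction.
"Sense" means the L1's strand equals its host gene's strand.

## Transcription Blocking Index

For a sense intronic L1, the upstream flank runs from the TSS-side gene
boundary to the L1 end nearest the TSS, the downstream flank from the L1
end nearest the TES to the TES — both defined in the transcription
direction, so for minus-strand genes "upstream" is the higher-coordinate
flank. `TBI = downstream FPKM / upstream FPKM` on the gene's strand: ~1
means elongation passes the element, < 1 means blocking. This orientation
of the ratio is fixed by the interpretation contract (smaller index =
stronger blocking), which is what all downstream statistics use.

Antisense L1s are rejected by definition. Two validity guards of this
implementation (the analysis they support states none): each flank must be
at least 500 nt, and the upstream FPKM at least 0.1 — a ratio against a
near-zero denominator carries no information. The L1 body itself is never
part of either flank; other L1 bodies within a flank are retained by
default (a config toggle can exclude them). Multi-L1 genes get one TBI per
sense L1 over that L1's own flanks, with no chaining. A per-gene TES
override supports genes whose annotated end mixes short isoforms.

Delta-TBI between a condition and a control is the per-(L1, gene) pair
difference, dropping pairs invalid in either condition; the summary
statistic is the fraction of pairs with a TBI decrease beyond a threshold
(default 0.1). TBI is invariant to rescaling a track by any c > 0, and
swapping the flank signals inverts the index.

## Shuffle enrichment and host-gene statistics

The shuffle null re-places each query interval uniformly at random over all
valid start positions within same-chromosome universe intervals, preserving
length, name and strand, without self-overlap enforcement. The default
universe is the transcribed regions (a genome-wide universe is a caller
choice), so the null respects where signal can occur at all. Enrichment of
observed vs expected overlap counts is reported two ways: a Fisher's exact
test of [observed hit, observed miss] against [rounded expected, rest] —
mirroring the observed-vs-expected construction the analysis popularized —
and an add-one-corrected empirical permutation p from the shuffles, the
statistically cleaner companion. Tests are two-sided by default, with no
multiple-testing correction across factors (a BH option exists).

Host-gene set enrichment intersects everything with the expressed-gene
background first; the expected overlap is `|set| x |hosts| / |background|`
and the p-value is Fisher's exact on the resulting 2x2.

Length-stratified fold changes sort genes by length into equal-count bins
(remainder to the longest bins, sizes differing by at most 1), report
per-bin mean log2 fold change with t-based 95% CIs, and fit OLS of fold
change on log10(length) with a slope CI.

## RRACH accounting

RRACH (R = A/G, H = A/C/U; the methylated A at position 3) is scanned on
the RNA sense strand only, U read as T, N never matching. Every matching
offset is counted, overlapping occurrences included — the exhaustive
convention, with a greedy non-overlapping mode for sensitivity analyses,
since published motif totals do not state their convention. Profiles bin
motifs by first base into 500-nt bins.

Mutant design samples `floor(fraction x count)` (at least one) motif
instances uniformly and substitutes the central A. The substitution is C by
default; in the one context where a C itself completes a new RRACH one
frame to the left (second R an A, with A/G three bases upstream), T is used
instead — A->T at a motif centre provably cannot create a new instance, so
a re-scan of the mutant never finds motifs absent from the original. A
substitution inside overlapping motifs can disrupt several instances at
once; the bookkeeping (counts on both sequences, positions lost, Hamming
distance, per-bin table) is exact.

The subfamily-level correlation between m6A level (MINT/TT FPKM ratio) and
estimated evolutionary age (supplied as a table; ages come from published
estimates, they are not computed here) is Spearman's rho, with a two-sided
exact permutation p by full enumeration for up to 10 subfamilies and the
t-approximation beyond.

## Synthetic data: what it emulates, and what it does not

The generator encodes the statistical structure the analysis assumes, not
the real data. A toy genome (two chromosomes, <= 20 Mb) carries
non-overlapping genes with log-uniform lengths (30–300 kb by default),
terminal 300 bp exons and at most 8 internal exons — the cap keeps introns
tens of kb long, as in the long genes that host intronic L1s. L1s
(500–6000 bp) are placed wholly inside introns, non-overlapping, sense to
the host with probability 1/3 (matching the ~1:2 sense:antisense ratio of
intronic L1s); only sense L1s can be methylated (probability 0.5 by
default). Methylated L1s get young subfamily labels and low divergence,
unmethylated ones older labels — flavour for the interval plumbing, not a
calibrated evolutionary model.

Coverage rates: TT is constant per gene body (per-gene rate log-uniform in
[0.2, 5]), multiplied by the blocking factor `b` (default 0.5) downstream
of each blocking L1's 3' end in the transcription direction; MINT is the TT
rate times the enrichment factor `e` (default 8) inside methylated L1s;
RNA keeps the gene rate on exons, decays introns to 5% (introns are rapidly
degraded; the exact factor is unstated in any source, so it is
configurable), and multiplies the stability factor `s` (default 3) inside
methylated L1s. Each assay is rescaled so its expected total equals the
requested depth (default 2e6 fragments) and counts are drawn Poisson in
50-nt bins; a negative-binomial toggle adds overdispersion for robustness
checks. Spike-ins: per-species input reads are Poisson around
depth/species with mild lognormal abundance jitter; IP reads are Poisson
with the per-molecule capture probability above (capture 0.9, background
0.05 by default) times a global IP library scale; ERCC species appear in
both libraries up to that same scale. RBP peaks hit methylated L1s with
probability `q_meth`, other L1s with `q_bg`, plus uniformly placed
background peaks over gene bodies. All generators are pure functions of
(params, seed), and a truth table records every L1's methylation,
orientation, blocking and stability exactly once.

Not emulated: raw reads and alignment ambiguity, mappability structure,
splicing isoforms, overlapping genes, fragment-length effects, position
within the L1 consensus, and any sequence-coverage coupling. Passing tests
therefore demonstrate that the estimators recover the quantities they
define under the stated noise model — not that the biological conclusions
of any particular dataset follow.

## Problem sizes and numerical choices

Simulation-backed checks use problem sizes chosen to make the statistics
sharp at desk scale: 30 genes / 2e6 fragments for MIL recovery (precision
and recall >= 0.9 at e = 8), 20 seeds at 1e5 input fragments per group for
spike-in unbiasedness (+-2 points), 20 seeds of a single 100 kb gene at
5e5 fragments for TBI recovery (|TBI - b| < 0.05 for b in {0.25, 0.5,
0.75, 1.0}) and for the null delta-TBI calibration (fraction beyond 0.1 in
<= 5% of pairs in >= 90% of seeds). Brute-force oracles (hypergeometric
enumeration for Fisher, all-offset motif matching, exhaustive cutoff scans,
full permutation enumeration) back the fast implementations in the test
suite. Ties: BH uses the standard step-up; Spearman mid-ranks ties; the
Super-MIL cutoff breaks slope ties toward the highest rank; degenerate
inputs (constant ranking curves, zero dynamic range, empty margins,
zero-input spike species) are flagged or refused rather than silently
propagated.
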