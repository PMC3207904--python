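# Methods

## Read-density model

All quantification is anchored on one TSS per gene (the strand-dependent 5′
base of the annotated span; alternative TSSs must be pre-collapsed by the
user). Reads are counted by their 5′ mapped position — `start` for
plus-strand reads, `end − 1` for minus-strand — with no fragment extension
or shift; a `midpoint` counting mode is exposed for comparison. This suits
short (36 bp) single-end reads where the fragment is not much longer than
the window. Windows are half-open `[c − w//2, c − w//2 + w)`; for odd
widths the upstream side holds one base fewer, which partitions the genome
without ties. In TSS metaprofiles the half-openness is mirrored on
minus-strand genes so profiles are exactly strand-symmetric.

The unit is RPM: window count × 10⁶ / total uniquely mapped reads. The
denominator is a property of the library, not of the stored records, so a
`MappedReadSet` may hold a genomic subset of a larger library. Whether
reads on unplaced contigs belong in the denominator is a data-provenance
question; the denominator is therefore user-supplied (or defaults to the
record count) and recorded in output.

A gene's per-mark status is the **exact** maximum of windowed RPM over
every integer center within ±flank of the TSS. Window coverage as a
function of the center is piecewise constant and increases only where a
read's coverage interval begins, so evaluating the count at each clipped
interval start (plus the flank boundary) equals the full sweep; the test
suite verifies equality against a literal all-centers scan. The statistic
feeds hard thresholds downstream, so grid approximations were ruled out.
Metaprofiles, in contrast, use a 10 bp step grid and average per-gene RPM
with equal gene weight (seed-robust; a pooled-read average would weight
deep promoters more).

Defaults: window 300 bp for H3K4me3 and Smad1, 500 bp for H3K27me3 and
MeDIP (the repressive mark's distribution around the TSS is broader);
flank ±2,000 bp for histone marks, ±1,000 bp for MeDIP.

## Status, transitions, categories

Thresholds (RPM): H3K4me3 (+) > 4, (−) < 3; H3K27me3 (+) > 1.5, (−) < 1.
The gap between the bounds is an explicit *indeterminate* zone: genes
indeterminate for a needed mark are reported in their own bucket, never
silently dropped. A transition requires crossing the whole gap
(loss: > hi then < lo), which makes calls robust to small fluctuations
around a single cutoff. Repressive-mark gain is the mirror image
(< 1.0 then > 1.5) of the loss rule, and the active-mark rules use the
same shape with the 4/3 thresholds.

Categories are assigned in fixed precedence order — K27→K4, Bi→K4,
K4→K27, (−)→K27, loss_only, gain_only, stable, other — and are mutually
exclusive and exhaustive by construction; precedence only matters under
degenerate custom thresholds. ΔH3K27me3 classes use an absolute change of
≥ 0.4 RPM in the per-gene maximum. The MeDIP hypermethylation rule is a
re-parameterization of the same machinery: < 2 RPM rising to > 4 RPM with
the MeDIP windowing.

## Expression

Global normalization scales each sample to mean 100. Fold change is
linear-scale (condition mean / baseline) with a score floor of 1.0 on both
sides; microarray scores near zero are noise-dominated and would otherwise
produce unbounded ratios. The floor is configurable. Ranking is descending
fold with ties broken lexicographically by gene id — determinism matters
because ranks are the input of the KS tests. The senescent condition is
summarized as the mean of the day-3/7/10 samples (configurable; using the
last day alone is a supported alternative). Differential sets use strict
> 5-fold / < 0.2-fold cutoffs; "active" genes have a maximum score > 25
across a stimulation time course.

## Enrichment statistics

The rank-enrichment test is a two-sample Kolmogorov–Smirnov comparison of
subset ranks against complement ranks within a stated background (never
the whole genome: transition categories are tested within their K27-loss
or K27-gain panel, binding-target strata within all targets). The
asymptotic p uses λ = (√n_e + 0.12 + 0.11/√n_e)·D with
n_e = n₁n₂/(n₁+n₂) and the alternating exponential series; a permutation
mode re-places the subset uniformly, exhaustively when the number of
placements is small. A one-sample mode (subset vs uniform) is exposed for
comparison.

Directionality is a substantive choice. Category reports use the
**one-sided** tail in the direction the category predicts (loss panels
upward, gain panels downward; p = exp(−2λ²)). A two-sided test is
structurally incapable of declaring a flat category null here: the flat
category's panel complement contains the coordinated genes, whose strong
expression shifts alone force a large two-sided D (of order
n_shifted/n_complement). The one-sided test asks the scientific question —
"is this category enriched in its predicted direction?" — and yields
p ≈ 1 for a category that is, if anything, displaced the other way. The
generic `ks_rank_enrichment` default remains two-sided, and the type-I
calibration (rejection rate at α = 0.05 within [0.03, 0.07] under uniform
placement) is verified for it. Permutation and asymptotic p agree within a
factor of two for group sizes ≥ 50 in the moderate-p regime.

Fisher's exact test (one-sided `greater` by default for enrichment claims,
two-sided by flag) is computed with scipy's hypergeometric machinery and
cross-checked in the tests against an exact rational enumeration of every
2×2 table with margins ≤ 12. No multiple-testing correction is applied;
reports carry the number of tests run.

## Smad1 site calling and assignment

No peak-calling algorithm is inherited from upstream work; the caller here
is deliberately minimal and fully parameterized. A 300 bp window slides at
step w/3; a window is significant when its count is ≥ 8 reads **and**
Poisson-improbable (upper tail p < 1e-5) under the genome-wide uniform
rate λ = reads × w / genome length; significant windows closer than 100 bp
merge; the summit is the center of the highest-count window (leftmost on
ties). There is no control-track subtraction or local background — planted
sites of ~30 reads are unambiguous against the default background, and the
expected number of genome-wide false windows at the defaults is below
0.05 per run.

Distance rules use the summit: within 10 kb of a gene *span* ("near a
gene") and within 5 kb of a TSS (defines a target gene). One summit within
5 kb of several TSSs marks all of them — assignment is one-to-many.
Signed summit→TSS distances are positive downstream in transcription
direction. Nearest-gene ties break to the lexicographically smaller id, so
re-running on shuffled input is bit-identical.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
a scale where a full run takes seconds:

* **Genome/annotation**: two 50 Mb chromosomes, 2,000 genes of 2–50 kb.
  Gene spans are placed by drawing lengths and distributing the leftover
  sequence as uniform random gaps with a 6 kb minimum — sampling uniform
  non-overlapping placements directly (no rejection) while guaranteeing
  that a gene's ±2 kb flank never overlaps a neighbour's promoter signal.
  The genome is large relative to a real gene-per-Mb density so that
  promoter windows are signal-attributable; the original annotation scale
  (tens of thousands of genes on Gb chromosomes) is not needed to exercise
  any code path.
* **Reads**: each track stores a Poisson-uniform background of 1.5 reads/kb
  plus, for each mark-positive gene, Poisson(budget) reads whose 5′
  offsets are Normal downstream of the TSS — mean +250 bp / sd 300 bp and
  budget 350 for the active mark; mean +500 bp / sd 700 bp and budget 180
  for the repressive mark (wider, as observed for Polycomb domains);
  sd 400 bp centered on the TSS for MeDIP. The per-million denominator is
  fixed at 10⁷ — the tracks emulate a genomic slice of a full sequencing
  library — which keeps the published RPM thresholds directly meaningful:
  positive genes land at ≈ 3× the high threshold and negative genes well
  below the low threshold, giving ≥ 99% status recovery for isolated
  genes.
* **Planted transitions**: category fractions 2% K27→K4, 0.5% K4→K27,
  5% Bi→K4, 9% (−)→K27, plus one-sided loss/gain contingents; stable genes
  split over baseline classes (50% active, 37% silent, 7% repressed,
  6% bivalent). Coordinated switches carry expression multipliers
  (×U(5,100) up, ×U(0.01,0.2) down); one-sided switches carry none.
* **Expression**: baseline scores lognormal with class means 300 (active),
  25 (silent), 12 (bivalent), 8 (repressed) and log-sd 0.8 — producing the
  expected mark/expression coupling — times per-day lognormal noise
  (log-sd 0.2). A separate stimulation time course induces binding-target
  genes ×U(3,10).
* **Binding**: each of the 100 target genes (5%, drawn from
  transition-stable genes so truths never collide) gets one Poisson(30)
  read cluster (sd 60 bp) at TSS + U(−5 kb, +5 kb); 20% as many decoy
  clusters are placed > 10 kb from every gene. A tenth of targets receive
  extra repressive-mark reads in the senescent condition (ΔK27 increase)
  with coupled repression, and 15% the reverse, mirroring the
  target-stratification analysis.
* **MeDIP**: 100 genes methylated in both conditions, 3 hypermethylated
  only in the second — the screen must return exactly those 3.

Each track draws from an independent generator seeded by
(master seed, crc32(track label)): adding a track never perturbs another,
and regeneration is bit-exact.

**What the generator does not emulate**: mappability and GC bias,
replicate/batch structure, fragment-length effects, chromatin domains
beyond single promoters, overlapping or nested genes, bidirectional
promoters, and any sequence-level features (no motifs). Passing tests
therefore demonstrate that the machinery recovers planted structure under
idealized noise, not that the thresholds are optimal for any particular
real library.

## Numerical and degenerate-input choices

* Exact integer-center sweep for per-gene maxima; profile grids at 10 bp.
* KS p-values floored at the smallest positive double, capped at 1.
* Enrichment of an empty subset, or a subset equal to its background, is
  reported as *untestable*, never as an exception in pipeline context.
* An unknown chromosome in a density query returns 0 RPM with a warning
  (absence of reads is data, not an error); a zero-length genome or empty
  read set in the site caller is an error.
* "." strands in BED input are stored as "+" (read strand only selects the
  5′ anchor, and the anchor of a 36 bp read moves by 35 bp — cosmetic at
  300–500 bp windows, and irrelevant for strand-balanced libraries).
* All table writers sort deterministically; re-running any stage on the
  same inputs is byte-identical apart from timestamps (which are excluded
  from the report body).

## Problem sizes used in the checks

The shipped test and acceptance runs use the default 2,000-gene bundle
(one seed end-to-end, 20 seeds at the expression level for the null
categories), 2,000 replicates for KS null calibration, 300 gene-status
oracle comparisons, and the complete enumeration of 2×2 tables with
margins ≤ 12 — sizes chosen so each property is measured with comfortable
statistical margin while a full run stays in the tens of seconds.

## Known limitations

* Hard thresholds have no error model; near-threshold genes are sensitive
  to depth differences between libraries (the indeterminate zone mitigates
  but does not remove this).
* The Poisson caller assumes a uniform background; on real data, open
  chromatin and copy-number variation inflate local rates and a control
  track would be needed.
* One TSS per gene: alternative promoters must be collapsed upstream.
* Fold-change ranking with a floor compresses genes whose baseline and
  condition scores are both near zero toward fold 1.
* The asymptotic KS p is approximate for very small subsets; the
  permutation mode (exact for tiny backgrounds) is the reference there.
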