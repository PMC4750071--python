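# Methods

This note documents the models and numerical choices behind
`capture_qc`: what each metric computes, what the synthetic-run
generator does and does not emulate, and where design decisions were
genuinely open.

## Coordinates and formats

All internal intervals are 0-based half-open (BED convention); VCF
positions stay 1-based at the file boundary and convert on read.
A capture design is a sorted, merged set of disjoint intervals;
abutting BED intervals are merged so that region counts are
deterministic. The common design of several methods is the base-level
intersection of their designs; all cross-method depth and variant
metrics are restricted to it.

An aligned proper pair is abstracted as one *fragment* with outer
coordinates (leftmost start, rightmost end). Improper pairs are
excluded by default (they can be admitted as single-end fragments via
a flag); unmapped, secondary and supplementary records are skipped
and tallied.

## Duplicate marking

Fragments sharing `(chrom, frag_start, frag_end, orientation)` form a
duplicate set; the member with the highest summed base quality stays
unmarked, ties broken by smallest read name. `orientation`
distinguishes innie pairs by which read is on the forward strand —
two pairs with identical outer coordinates but swapped read1/read2
strands are different library molecules. Marking is flag-only:
duplicates remain in the stream so raw and duplicates-excluded
metrics can both be computed. Duplicate *read* fractions count both
reads of each pair.

Coordinate-keyed marking cannot distinguish a PCR copy from two
independent fragments that happen to share coordinates. At high depth
over a small design these coincidental collisions inflate the marked
fraction by a predictable amount (~0.1–0.5 % absolute in the
configurations used here); the parameter-recovery checks therefore
run at panel scale (~300 kb) where the excess is an order of
magnitude below the Monte-Carlo tolerance.

## Coverage statistics

Depth at a targeted base counts aligned read *blocks* (CIGAR M
segments) covering it: both mates contribute, overlapping mates
double-count, and deleted reference bases (CIGAR D) contribute
nothing — this reproduces `samtools depth` semantics exactly, and one
test asserts per-base equality against samtools as an independent
oracle.

The evenness score is

    ES = 100 · (1/m) · Σ_{i=1..m} F(i),   m = ⌊C̄⌋,

with C̄ the mean depth over targeted bases and F(i) the fraction of
bases at depth ≥ i. Uniform coverage gives exactly 100 at any depth.
The floor-of-mean discretisation makes ES only *asymptotically*
invariant to depth rescaling: multiplying a shallow profile's depths
by an integer can move ES by a few points (e.g. depths
{1,1,1,1,4,4,4,4}: ES = 75 at C̄ = 2.5 but → 70 as the profile is
scaled up). At panel-scale means (hundreds of X) the effect is
negligible, and the property test asserts invariance to within one
point at C̄ ≈ 80. For C̄ < 1 the score degenerates to 100 · F(1) and
a warning is logged. Threshold tables use non-strict inequality
(≥ t); distribution curves use strict (> d), in both per-region
(mean depth) and per-base variants.

Per-region normalised depth is nDOC_i = aDOC_i / aDOC with aDOC the
length-weighted design mean, so the length-weighted mean of nDOC is
exactly 1. GC per region is (G+C)/(A+C+G+T) with N excluded from both
numerator and denominator; GC bins are `floor(gc / w)` with default
width w = 0.05. Per-region mapping quality is aggregated as RMS
(matching the VCF "RMS mapping quality" convention); regions below a
floor (default 20) are flagged as pseudogene-suspect, and regions
with no reads are reported as `no_data`, distinct from low MAPQ.

## Enrichment

A read is on-target iff its span overlaps the (optionally padded,
default 0) design by ≥ 1 bp. The Enrichment Factor uses the on-target
*base* fraction — EF = base fraction × genome size / target size —
because base-level accounting is insensitive to read length; both
read and base fractions are reported so either convention can be
inspected. Defaults are raw (duplicates included), the convention for
a raw on-target percentage; the genome size defaults to the sum of
reference contig lengths, with the hg19 constant (3,095,693,983 bp)
provided for real human runs.

## Variants

Variant identity is the exact key (chrom, pos, ref, alt) after
multi-allelic decomposition and left-normalisation (shared trailing,
then leading, bases trimmed; no fuzzy indel matching). Concordance
over three callsets reports the seven Venn cells and *includes*
filtered calls — discordance is frequently created by filtering, and
excluding filtered calls would hide it. Allele-balance and QUAL/MQ
summaries conversely use PASS calls only. Ts/Tv counts A↔G and C↔T as
transitions over SNVs; zero transversions yields an infinite ratio
with a warning rather than an error. Truth-set sensitivity is exact
key membership; each miss is reported with any call within ±10 bp and
its allele balance, the forensics needed when a variant is present in
the reads at reduced allele fraction but absent from a callset.

## Paired comparisons

Method pairs are compared with one-sided Wilcoxon signed-rank tests
on per-sample values. Zero differences are dropped (Wilcoxon's
original rule); absolute differences are ranked with average ranks
for ties. For n ≤ 25 effective pairs the p-value is exact: the null
distribution of W⁺ is built by a generating-function pass over the
doubled ranks (doubling keeps tied .5 ranks integral), which is
equivalent to full 2ⁿ enumeration and is verified against it in the
tests. Beyond 25, a tie-corrected normal approximation with
continuity correction is used. The default α is 0.025 (one-sided);
no multiple-testing correction is applied to the significance flag,
but a Bonferroni-adjusted column is emitted. Because the exact null
is discrete, the attained size at α = 0.025 is slightly conservative
(~0.023 empirically at n = 24).

## The synthetic-run generator

The generator emulates the statistical structure the QC metrics
assume, not sequencing physics:

* **Reference** — quota-sampled bases per GC block (exact block GC up
  to rounding, positions shuffled), so GC landscapes are controlled
  to within rounding error. No repeats, no N runs.
* **Design** — exactly `n_regions` disjoint regions (default
  150–250 bp, ≥ 200 bp apart) allocated proportionally across
  contigs with random slack, mimicking an exons ± flanks panel.
* **Placement** — each unique fragment is on-target with probability
  `on_target_prob`. An on-target fragment is drawn so that *both*
  read spans overlap the design; an off-target fragment so that
  neither does. The flag is fixed before placement rejection, making
  the read-level on-target fraction an unbiased Bernoulli estimate of
  the preset probability — a boundary-straddling placement rule would
  bias the read-level fraction below the fragment-level one.
* **Fragment lengths** — Normal(frag_mean, frag_sd) rounded and
  truncated at twice the read length (default read length 100 bp, so
  mates never overlap and reads never extend past the fragment).
* **GC response** — optional rejection sampling on fragment GC
  (`gc_dropoff` gives the canonical flat-then-linear falloff above
  65 % GC). Presets default to a flat response; the response shapes
  *where* fragments land, not the on/off-target split.
* **Duplication** — each unique fragment is sequenced k times with
  k − 1 geometric (memoryless amplification, the simplest
  one-parameter model). For this parameterisation
  E[1 − unique/total] = 1 − p, so p solves in closed form from the
  preset duplicate fraction. PCR copies share the fragment's alleles
  but get independent sequencing errors and qualities.
* **Depth calibration** — when the pair count is not given, a
  4,000-fragment pilot estimates the mean on-target read bases per
  fragment and the total pair count is set to hit the preset raw mean
  DOC (realized depth lands within ~1 %).
* **Variants** — spiked at distinct design positions; SNV types drawn
  with transition probability t/(1+t) for a target Ts/Tv of t; indel
  lengths 1–6 bp with wide exclusion windows (no second variant
  inside a read carrying an indel) and, when any indel is requested,
  one forced 6 bp deletion — the classic missed-variant scenario.
  Alleles are assigned per *fragment* (het carriers with probability
  0.5), injected into read sequences with correct CIGARs before
  per-base errors; an indel only partially covered by a read is left
  unapplied, as in a real alignment. An optional reference-bias
  parameter drops alt-carrying fragments for allele-balance
  experiments.
* **Qualities and errors** — two-point base qualities (Q37/Q22) with
  P(Q37) = `q30_fraction`; uniform per-base mismatch errors at
  `error_rate`. No quality decay along the read, no indel errors, no
  aligner artifacts.
* **MAPQ** — 60 everywhere except inside declared pseudogene-like
  blocks, where it is drawn from {0..10}; homology itself is not
  modelled.
* **Callsets** — variant calling is upstream of this package, so
  per-method callsets for concordance experiments are simulated
  downstream of the shared truth: one latent allele fraction per
  variant, Poisson depth and binomial allelic depth per method, and
  detection thresholds on allele fraction and read support, which
  ties dropout to low allele balance.

Everything is deterministic given (seed, parameters); two runs with
the same seed produce byte-identical SAM/VCF output.

### Method presets

| preset | frag mean/sd (bp) | on-target | dup fraction | raw DOC |
|---|---|---|---|---|
| nimblegen | 250 / 60 | 0.86 | 0.077 | 370X |
| qxt | 320 / 110 | 0.75 | 0.185 | 370X |
| nrcce | 250 / 85 | 0.85 | 0.412 | 371X |

Duplicate fractions, on-target fractions and depths are the published
per-method rates; fragment-size parameters are chosen only to respect
the published *ordering* (QXT longer and more dispersed, NRCCE more
dispersed than NimbleGen), as the source reports no numeric medians
in its main text.

### What passing tests do and do not show

Recovery tests show that the pipeline's estimators are unbiased and
correctly calibrated under the generative model — coordinate dedup
recovers the duplication rate, overlap counting recovers the capture
probability, depth accounting is internally consistent
(raw × (1 − dup) ≈ dedup), spiking recovers the transition bias. They
do not validate behaviour on real data features the generator omits:
repeats and mappability structure, indel-rich loci, quality decay,
strand bias, batch effects, or genuine probe thermodynamics.

## Problem sizes

Recovery checks use ~120k read pairs over a ~300 kb design (1,500
regions); the depth-accounting check uses a ~60 kb design (300
regions) at the full 371X preset depth (~200k pairs); Ts/Tv recovery
spikes 10,000 SNVs; the type-I-error check runs 10,000 exact tests at
n = 24. These sizes put Monte-Carlo noise well inside the stated
tolerances while keeping a full run of the suite plus the acceptance
script under a few minutes.

## Known limitations

* Coordinate dedup counts coincidental coordinate collisions as
  duplicates (as any coordinate-keyed implementation does); no
  optical-duplicate or UMI logic.
* The fragment model has no chimeras, no adapter read-through, no
  soft-clipping; CRAM is not supported.
* Concordance is exact-key only; complex-region equivalence of
  represented indels is out of scope.
* The Wilcoxon table tests both directions for every pair; the
  direction of a one-sided hypothesis is the caller's choice, not
  inferred from the data.
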