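# Methods

## The screening model

The screen operationalises "strong constitutive promoter" as a property
of the downstream gene: a gene whose expression is in the top fraction
*f* of all genes in **every** sampled condition. Raw read counts are
used as the expression measure, so the ranking reflects transcript
abundance per gene rather than per kilobase; long genes are favoured by
this choice. We keep raw counts as the default because pooled-replicate,
single-library-per-condition designs make the per-sample ranking
scale-free (any per-sample normalisation that is monotone leaves the
ranking unchanged), and expose an optional CPM mode (`cpm=True`) for
designs with very different library sizes. No length correction is
applied; the bias is documented, not removed.

The cutoff size is *k* = ⌈*f·n*⌉. Ceiling rather than floor guarantees a
non-empty top set for any non-empty input; for *n* = 4427 and *f* = 0.03
this gives *k* = 133. Ties at the boundary are resolved by a total order
(descending count, then ascending gene id) and truncated at exactly *k*;
because published analyses rarely state their tie convention, a
tie-inclusive mode (`boundary="ties"`) that admits every gene tied with
the *k*-th is provided. Replicate columns, when present, are summed per
condition before ranking (`aggregation`), matching designs where
replicates are pooled before sequencing.

The intersection requires qualification in all samples by default;
`min_samples` relaxes this to ≥ *m* of *S* for sensitivity analyses.
Genes present in the count table but absent from the annotation are kept
through selection and reported in a separate list, never silently
dropped.

## Upstream intergenic regions

The promoter region of a candidate gene is purely positional: the
intergenic span between the gene's 5′ boundary and the nearest annotated
feature boundary on its 5′ side, regardless of the neighbour's strand
(the neighbour's strand is recorded for auditing; convergent and
divergent arrangements are not distinguished). Feature classes that
bound regions are gene, CDS, rRNA, tRNA, tmRNA and ncRNA — non-coding
RNA genes have promoters too, and their boundaries delimit intergenic
space exactly as CDS boundaries do.

Coordinates are 0-based half-open internally (BED convention);
GenBank/GFF3 1-based inclusive coordinates are converted only at I/O.
On circular replicons the search wraps across the origin, implemented as
modular distance from the gene's 5′ anchor to each candidate boundary;
the gene's own far end participates as a candidate so that a gene with
no 5′ neighbour correctly gets the whole non-genic remainder of the
circle. Rotating all coordinates by a constant offset leaves every
region length unchanged (tested). On linear replicons a gene with no 5′
neighbour is truncated at the replicon edge and flagged. An overlapping
or abutting upstream neighbour yields length 0 — never negative.

The length filter excludes regions **shorter than** the threshold
(default 100 bp): a region of exactly 100 bp passes. Extracted sequences
are oriented 5′→3′ relative to the candidate gene (reverse-complemented
for minus-strand genes). Promoter ids are "P" + the trailing digits of
the locus tag, giving stable, human-readable names.

Degenerate inputs: origin-spanning gene records (a single feature
crossing the origin) are not represented; synthetic genomes never
produce them and real annotations that contain one should be rotated
first. Nested genes are handled by the overlap rule (length 0 for the
inner gene's promoter when the outer covers its 5′ anchor).

## Synthetic study bundles

The generator emulates the data the screen consumes, with known ground
truth:

- **Genome**: genes of uniform length 200–1200 bp packed around a
  circular replicon (default 250 kb, 200 genes) separated by gaps drawn
  from a two-part mixture — a fraction `frac_short_gap` (default 0.3)
  uniform on 10–99 bp, the rest uniform on 100–600 bp — so the length
  filter has a controllable number of true exclusions. Leftover length
  is absorbed into the origin-wrap gap. Strands are random. Each gene's
  true upstream gap is computed by a sorted-neighbour walk inside the
  generator, independent of the extraction code it is used to test.
- **Counts**: negative binomial with var = m + α·m², α = 0.01 by
  default (high-abundance genes are weakly overdispersed). Background
  mean 50; constitutive genes mean 50 000 (1000×) in every sample;
  condition-specific decoys mean 10 000 (200×) only in an assigned
  non-empty *strict* subset of the samples. Keeping decoys well above
  background but well below the constitutive mean makes recovery a
  property of the design rather than of lottery tie-breaks: however many
  decoys land in one sample, they cannot push a constitutive gene out of
  the top fraction (separation ≈ 8 background sds). Decoy subsets are
  drawn to cover all samples where feasible, so the boundary slot of
  each sample is a decoy, not a random background gene. Sequencing depth
  is chosen for separability — real per-condition depth is not modelled,
  nor are batch effects, gene-length effects or correlated biological
  replicates, so passing tests demonstrate the pipeline's logic, not its
  robustness to those real-data features.
- **Assay tables**: built by inverting each quantitation formula from
  known true parameters (promoter strengths in % of reference,
  activities, ammonium concentrations, ΔΔCt fold-changes), with
  multiplicative Gaussian noise of configurable coefficient of
  variation (additive in Ct cycles); `noise=0` makes recovery exact,
  which is the basis of the round-trip tests.

All randomness flows from a single integer seed per bundle; generation
is deterministic and byte-stable.

## Assay formulas and numerical choices

- Luciferase strength uses blank (promoterless-vector) subtraction by
  default, with a flag to disable; negative blank-subtracted signals are
  clamped to 0 with a warning. The reported sd is the replicate sd
  scaled by the reference denominator (ratio-of-means approximation —
  reference-side variance is not propagated).
- The acetylene-reduction formula takes the GC peak-area ratio to the
  1 nmol ethylene standard, scales by the 100 mL headspace and divides
  by protein mass × 4 h. The injected aliquot volume is recorded but
  does not enter the arithmetic (it cancels against the identically
  injected standard).
- The ammonium standard curve is fitted with an intercept (not forced
  through the origin); r² < 0.98 triggers a warning; inversion outside
  the standard range returns the value with an extrapolation flag.
- qPCR efficiency is fixed at 2 (perfect doubling); no efficiency
  calibration is modelled.
- Fold ratios are rounded half away from zero.
- ANOVA uses the classical decomposition; Tukey HSD p-values come from
  the studentized-range distribution (scipy). Two identical groups give
  F = 0, p = 1. The degenerate case of zero within-group variance with
  unequal means has no finite F; it is reported as p at the machine
  floor with an explicit `degenerate` flag rather than NaN.

## Problem sizes used in the test and acceptance runs

Default bundles are 200 genes × 4 samples; planted-truth recovery is
checked over 20 seeds. The study-scale reconstruction uses 4427 genes on
a 4.8 Mb replicon with 39 planted constitutive genes (13 behind short
gaps) and 10 decoys, screened in a few seconds. These sizes exercise
every code path at the scale of a real bacterial genome while keeping
the full suite fast.

## Known limitations

- Upstream regions are defined by annotation geometry only; no TSS
  mapping, operon inference or −10/−35 motif analysis, so a gene inside
  an operon gets its nearest-neighbour gap, not its true promoter.
- Raw-count ranking inherits gene-length and depth biases (see above).
- Whether the 100 bp threshold should apply to the intergenic gap alone
  or to a cloned fragment with flanking context is a judgement call; the
  gap-only reading is implemented.
- Fold-change language ("increased by x-fold" vs "x times higher") is
  reported as the plain ratio a/b; no +1 convention is asserted.
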