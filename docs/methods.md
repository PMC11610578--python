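# Methods

## Differential reference regions

Given a pairwise whole-genome alignment of a query assembly onto a template
assembly (PAF, 0-based half-open), the covered set is the union of aligned
target intervals of all blocks with mapping quality at or above a threshold
(default 0 — any alignment counts, the most faithful reading of "not covered
by the query"). DRRs are the complement of that set within the template
sequence dictionary, **minus known assembly gaps, then** size-filtered:
subtraction precedes filtering, so a gap can split an uncovered run into two
sub-threshold pieces that are then dropped. The size filter is strict
(`size > min_drr_size`, default 10 000 bp); the boundary case of exactly
10 000 bp is excluded, and the threshold is configurable. No merging across
gaps and no proximity merging of nearby DRRs is performed. All arithmetic is
exact integer interval algebra (sorted disjoint runs per sequence) rather
than binned coverage: binning would make results depend on an arbitrary bin
size, while interval arithmetic is deterministic and checkable against a
per-base boolean-array oracle, which the test suite does on ≤100 kbp
templates.

Secondary/supplementary PAF records are retained at parse time; filtering is
a downstream policy via the MAPQ threshold. Summaries report count, total
bp, min/median/max; the median is the lower of the two central values for
even counts, so it is always an observed region size.

Multi-way "shared missing" analysis sweeps the boundary points of all
per-query DRR sets and accumulates exclusive Venn partition sizes in bp,
keyed by the subset of queries each template base is missing from; partition
sizes sum exactly to the union size. Output is the numeric partition table —
the quantity of interest — rather than a drawn diagram.

## Annotation

Repeat fractions are exact base counts: per class, the union of that class's
features intersected with the region; in total, the union across classes —
so overlapping annotations (which RepeatMasker output can contain) never
push the total above 1, and per-class fractions may sum to more than the
total. "Fully repetitive" requires exact tiling (`total_repeat_fraction ==
1` in integer bp), avoiding floating-point tolerance. Centromere proximity
means a gap of at most `context_window` (default 10 000 bp, overlap counts
as 0); segmental-duplication membership means ≥1 bp overlap — no minimum
overlap fraction is imposed, and both choices are configurable.
Low-complexity repeats are reported as their own class, separate from
interspersed-repeat classes.

## Population presence

Per sample, the length-weighted mean depth over a DRR (absent BedGraph steps
count as depth 0) is classified: **present** strictly between `presence_lo`
(8×) and `presence_hi` (100×); **absent** at or below 8×; **no_call** at or
above 100× (a collapsed repeat attracting reads from multiple copies). Both
boundaries being open in the defining inequalities, each boundary value is
assigned to the adjacent conservative class (8× → absent, 100× → no_call)
and the thresholds are configurable.

Per cohort, the presence fraction is `n_present / n_total` with **no_call
samples kept in the denominator** (the cohort size is the fixed panel size);
a DRR is *not_detected* when zero samples are present, *rare* up to 5%,
*common* above 5%, and flagged *high_frequency* above 90%. Defining
not_detected as zero present samples (rather than a cohort-mean depth below
8×) keeps the three classes a partition of the DRRs. Mapping summaries use
primary records overlapping the DRR by ≥1 bp: the fraction with MAPQ
strictly above 20 and the multimapping fraction, where a read is
multimapping if an explicit hit-count tag exceeds 1 or several
non-supplementary records share its name. With zero overlapping reads the
fractions are undefined and flagged, not zero.

## Breakpoint junctions

A junction input is the derivative sequence plus two reference flanks
oriented 5'→3' as they appear in the derivative; handling inversion
orientation is the caller's duty (flank B arrives pre-reverse-complemented),
keeping the core string matching strand-agnostic. Resolution is maximal
exact extension: `a_end` is the longest derivative prefix equal to a suffix
of flank A, `b_start` the offset of the longest derivative suffix equal to a
prefix of flank B. Overlap (`b_start < a_end`) is microhomology; a gap is an
insertion; equality is blunt — microhomology and insertion are mutually
exclusive by construction, and the reported breakpoint placement is the
leftmost (maximally A-extended) one, a fixed convention since placement
under microhomology is inherently ambiguous by its length. Each flank must
anchor with an exact, unique match of at least `min_anchor` (default 15 bp);
ambiguity raises an error listing candidate offsets.

Insertions are *templated* when the full insertion or its reverse complement
occurs in a reference window around either breakpoint — exactly, or at ≥90%
identity over the full length (edit-distance infix search via edlib) —
otherwise *random*.

Per-side junction indels of a two-junction rearrangement use the signed
convention `indel = -(c2 - c1 - 1)` on each side's (left-aligned) breakpoint
coordinates in junction order: bases strictly between adjacent breakpoints
belong to neither derivative segment (deletion, negative); breakpoints that
overshoot duplicate the overlapped bases in both segments (positive);
adjacent coordinates give 0. Published junction tables are not always
expressible in a single coordinate convention, so this sequence-level
definition is authoritative for this package.

Inversion span is `|pos_b - pos_a|` of the defining junction, reported also
as Mbp rounded half away from zero and as a fraction of the chromosome.

Mechanism inference is a first-match cascade: (1) **NAHR** when a junction
has both breakpoints in same-name repeats with paralog identity ≥95% (no
published identity threshold exists for the resolved cases, so 95% is a
configurable default); (2) **complex MMBIR** at ≥3 junctions; (3) **MMBIR**
at any junction indel of ≥100 bp magnitude; (4) **MMEJ** at maximal
microhomology ≥2 bp; (5) **NHEJ** otherwise. Insertions alone — random or
templated, at the ≤90 nt sizes observed at non-replicative junctions — do
not trigger MMBIR; this is the minimal rule set consistent with the nine
resolved inversion labels the test suite reproduces.

## Synthetic data

The generator emulates the analysis inputs at desk scale. Defaults: 2
chromosomes × 300 kbp with 3 implanted segments of 12–20 kbp (repeat
fraction 0.3–1.0 as tandem 2–6-mer arrays, recorded in RepeatMasker-style
`.out`), one 2 kbp N-run assembly gap per chromosome, and an identity PAF
(one block per maximal shared non-gap segment, MAPQ 60) on which calling
returns the truth intervals exactly. Depth panels: 50 samples, per-region
allele frequency drawn in 0.1–0.9, per-100-bp-step Poisson depth at 30×
(present, the cohort's sequencing depth), 1× (absent: residual mismapping,
comfortably below the 8× cutoff) and 150× (collapsed repeats, above the
100× cutoff); Poisson was chosen as the simplest noise model that exercises
the thresholds — no overdispersion is claimed for real data. Read summaries
are emitted for the first five samples (matching the scale at which mapping
quality is typically audited) with a 1.3% multimapping fraction and ~20% of
reads above MAPQ 20. Junction simulation engineers microhomology by copying
the flank-A suffix into the flank-B prefix, and insertions either copied
from a breakpoint window (templated, reverse-complemented half the time) or
rejection-sampled to be absent from both windows (random); insertions
shorter than 8 bp are always templated, since any such k-mer occurs by
chance in a kbp-scale window. All randomness flows from one integer seed;
identical configurations produce byte-identical files.

What the generator does **not** emulate: sequence divergence between
genomes (alignment blocks are exact), alignment artifacts and chimeric
blocks, GC-dependent coverage bias, overdispersed depth, duplications or
other SV types beyond implanted absence and engineered junctions. Passing
tests therefore demonstrate the correctness of the interval arithmetic,
classification rules and junction string matching under the stated model —
not robustness to real aligner output.

## Problem sizes and determinism

Tests run the generator at the 2×300 kbp scale (20 seeds for truth
recovery, 50-sample panels, a 61-point microhomology/insertion grid); the
acceptance script uses a 4×1 Mbp genome for the self-comparison null. These
sizes were chosen so the full interval algebra, thresholds and junction
grid are exercised exhaustively while the whole suite runs in seconds.
Property tests are seeded; hypothesis-driven cases assert exact equality
with independent per-base oracles, so they hold for every generated
example.

## Known limitations

* NAHR detection requires caller-supplied repeat context with a paralog
  identity; the package does not align repeat copies itself.
* Junction resolution assumes exact anchors; a junction with sequencing
  errors inside the anchor region is reported unresolved rather than
  fuzzily matched.
* Gene-content annotation of DRRs and of junction breakpoints is input
  metadata, not computed.
* The cohort classes assume one depth track per sample over the DRRs;
  genotype likelihoods and copy-number estimation are out of scope.
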