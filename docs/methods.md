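# Methods

## Scope and data model

The package operates on three inputs it never produces itself: a pairwise
whole-plastome alignment (aligned FASTA, exactly two records, one
designated the reference), a feature table of annotated intervals on the
ungapped reference (coding / intron / spacer / rRNA / tRNA), and per-marker
multiple alignments with a sample→species map. Alignment production
(MAFFT or any other aligner, possibly manually adjusted) is deliberately
outside the computational boundary: it is not reproducible computation,
and all downstream statistics are conditional on the alignment given.

Coordinates are 0-based half-open internally and 1-based inclusive in all
files and reports. Sequences are upper-cased on input; any symbol outside
{A,C,G,T} — IUPAC ambiguity codes, N, gaps — is missing data at that site
for every analysis (the pairwise-deletion convention). Columns gapped in
every record are dropped at load (counted and logged), so a gap column
always belongs to exactly one sequence of a pair.

## Genome comparison

**Substitutions.** Every column where both genomes carry an unambiguous
base and the bases differ is one event. The six-type spectrum collapses
each event with its strand complement (C→T ≡ G→A, T→C ≡ A→G, C→A ≡ G→T,
A→C ≡ T→G, C→G ≡ G→C, A→T ≡ T→A), reference base first. Transitions are
purine↔purine / pyrimidine↔pyrimidine; Ts/Tv ratios are reported overall
and per annotation region (to 2 decimals, flagged undefined at zero
transversions). Positions in no annotated interval are "spacer" when they
lie between annotated features and "unannotated" otherwise.

**Indels.** One event per maximal gap run in a single sequence; the event
records the run length and which sequence carries the gap. Polarity
(insertion vs deletion) is not assignable without an outgroup, so the
package reports the gap carrier and lets report text phrase polarity
relative to the reference. Terminal gap runs are missing sequence ends,
not indels. The length histogram uses bins 1–10 bp plus a >10 bp tail.

**Microinversions.** Candidate loops are maximal runs of ≥ `min_loop`
(default 5) consecutive mismatching or gapped columns, at most `max_loop`
(60) long. A candidate is accepted when the reverse complement of the
reference segment equals the other genome's segment within
`max_loop_mismatch` (default 0) differences. The hairpin stem — the
inverted repeat flanking the loop in the reference itself — is grown by
greedy outward extension up to `max_stem_scan` (60) and reported when
≥ `min_stem` (3). Because an inverted segment read column-by-column would
masquerade as a dense block of substitutions, accepted loops are excluded
from substitution counting by default (`--no-inversion-masking` disables
this; whether published substitution totals exclude inversion columns is
generally not stated, so the choice is exposed).

## Diversity scan

π is the mean over unordered pairs of (pairwise differences / pairwise
comparable sites). Two gap-handling modes exist: pairwise deletion
(default — maximises data use for distances) and complete deletion
(drop any column with a gap/ambiguity anywhere; used internally for
haplotype identity, where a common site set is required). No n/(n−1)
correction is applied by default: for a two-sequence genome comparison the
correction simply doubles π, which is not the scale used for hotspot
screening; the corrected estimator sits behind a flag.

The sliding window (600 columns, step 25 by default) is defined on
alignment columns: gap columns count toward the window span but not toward
compared sites; the final partial window is dropped; an alignment shorter
than one window falls back to a single full-length window with a warning.
Hotspots are maximal runs of consecutive windows with π above the
threshold (default 0.012), merged into one interval from the first
window's start to the last window's end. When two runs are separated by
less than one window length the merged intervals can overlap; they are
still reported as distinct hotspots, since merging them would hide the
dip between peaks.

Marker statistics per alignment: aligned length; variable sites (≥ 2
distinct unambiguous bases in the column); parsimony-informative sites
(≥ 2 of those bases each carried by ≥ 2 samples); π; indel events counted
as distinct (start, length) maximal gap runs; haplotypes counted as
distinct sequences under complete deletion. Percentages are reported to 2
decimals.

## Discrimination and the mini-barcode search

K2P distances use pairwise deletion; entries are undefined (NaN) when no
site is comparable or the log arguments are non-positive, and undefined
entries are excluded from every minimum. The nearest-neighbour set of a
sample is all non-self samples at the minimum defined distance. The
default tie rule is strict: any heterospecific member of a tied set fails
the sample (the conservative reading of "closest distance belongs to one
conspecific individual"); `tie_rule="any"` accepts mixed ties containing a
conspecific. A sample with no defined distance fails. Pm = 100 ×
(successes / samples).

The window scans slice alignment columns; gap columns inside a window
count toward its nominal length. Window offset step is 1 column — the
familiar 10 bp granularity applies to window *length*, not offset. The
shortest-mini-barcode search computes the full-length discriminated-sample
count first, then scans lengths start (50), start+10, …, returning the
first length whose best window equals the full-length count. Counts, not
percentages, are compared: 11/12 discriminated prints as 91.67% but must
match exactly as an integer. Argmax ties break toward the smallest window
start. The empirical Pm-vs-length curve is recorded as scanned without
assuming monotonicity. Tree-based (NJ) discrimination is out of scope;
only the distance criterion is implemented.

Internally all window statistics come from per-pair prefix sums of
per-column site classes, so a window's distance matrix costs O(pairs)
rather than O(pairs × window length); tests verify exact agreement with
direct per-window recomputation and, for the K2P estimator itself, with
the independent implementation in R's `ape` (`dist.dna`, model K80).

## Synthetic data: what it emulates, what it does not

`simulate_genome_pair` plants, into a uniform-random 50 kb ancestor
(default), 150 substitutions with transition probability κ/(κ+2) per event
(κ = 2.86 by default, the Ts fraction ≈ 0.59 typical of congeneric
plastome pairs), 50 indels (63% single-bp, geometric tail capped at
34 bp, gap carrier random), and 3 hairpin microinversions (loops 14–19 bp,
stems 5–12 bp, loop constructed so its reverse complement differs at every
position, giving one unbroken mismatch run). Events are placed by
rejection sampling with a two-column separation margin, so planted truth
is recoverable exactly — which is the point: the generator's event record
is the oracle for the comparison stage. The feature table partitions the
sequence into alternating 1 kb coding / 500 bp unannotated intervals.

`simulate_marker_dataset` uses a star phylogeny only: a per-species
consensus mutated from a shared ancestor at the between-species divergence
(optionally confined to a diagnostic block, which then uses a high
per-site rate such as 0.3 so that ~12 diagnostic sites land in a
40-column block), then individuals mutated from their consensus at the
within-species divergence. Defaults (8 species × 3 samples, between 0.02,
within 0.001) reproduce the canonical barcoding design: a genus-scale
panel with every species represented by multiple accessions and a clear
barcode gap. No coalescent structure, no rate heterogeneity across sites,
no recombination, and no indels in marker mode (keeping the distance
oracles closed-form).

Passing tests on this generator therefore demonstrate algorithmic
correctness — exact event recovery, exact agreement with exhaustive
enumeration — not robustness to real-data pathologies such as alignment
error, heteroplasmy, nuclear plastid pseudogenes or shared haplotypes
between recently diverged species, all of which can depress real-world
discrimination below the synthetic figures.

## Numerical and design choices

- Distances and π are float64 throughout; undefined values are NaN, never
  sentinel numbers. Equality of tied distances is exact float equality,
  which is safe because ties arise from identical (transition,
  transversion, comparable) count triples.
- The problem sizes in the test suite and acceptance script — 200 random
  alignments up to 600 columns and 12 samples, 50 genome pairs of 50 kb —
  were chosen as the smallest sizes at which every code path (undefined
  distances, ties, partial windows, all three event classes) is exercised
  while exhaustive oracles remain exact.
- Pipeline runs write a manifest (tool version, parameter snapshot, input
  and output SHA-256 checksums, warnings); re-running an identical
  configuration reproduces identical checksums.
- Stage hand-off is deliberately manual between hotspot calling and marker
  evaluation: hotspots must be re-amplified and resequenced across the
  taxon panel (or sliced from a multi-genome alignment) before
  discrimination analysis, a wet-lab link no pipeline can compute.

## Known limitations

- Inversion detection assumes the inverted segment is short and flanked by
  a detectable inverted repeat; large rearrangements and IR boundary
  shifts are out of scope.
- The mini-barcode search optimises discrimination only; it does not check
  primer design feasibility of the winning window (primer thermodynamics
  is out of scope).
- With markers whose discrimination comes from indel patterns rather than
  substitutions, K2P-based Pm understates their value; indels are reported
  but never scored.
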