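# minibarcode

Design taxon-specific DNA mini-barcodes from chloroplast (plastid) genome
comparison.

Conventional plant barcodes (*rbcL*, *matK*, *trnH–psbA*, ≳650 bp) fail on
degraded DNA — processed medicinal herbs, canned food, decoctions, old
specimens. A *mini-barcode* is a short sub-region (~50–280 bp) of a marker
that amplifies from fragmented DNA while keeping the marker's species
discrimination power. This package implements the whole-plastome strategy
for finding the best mini-barcodes for a focal genus:

1. **Compare** two congeneric plastome sequences from a pairwise alignment:
   point substitutions (strand-collapsed six-type spectrum, Ts/Tv by
   annotation region), indels (maximal gap runs), and hairpin-flanked
   microinversions.
2. **Scan** the alignment with sliding-window nucleotide diversity
   (π, 600 bp windows, 25 bp step by default) and call divergence hotspots
   (π > 0.012).
3. **Evaluate** candidate markers resequenced across the genus by
   nearest-neighbour species discrimination on Kimura 2-parameter (K2P)
   distances.
4. **Shorten** each marker: find the shortest window whose best placement
   discriminates as many samples as the full-length marker.

It is aimed at molecular ecologists and barcoding practitioners working on
small genera (conservation forensics, food/medicine authentication) who
have a pair of congeneric plastomes and per-marker multiple alignments in
hand. The package consumes alignments (aligned FASTA); it never aligns —
produce inputs with any standard aligner (e.g. `mafft --auto`).

## The statistics at the core

**K2P distance.** For a sequence pair with transition proportion *P* and
transversion proportion *Q* over the pairwise-comparable sites (both bases
in {A,C,G,T}),

    d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)

undefined (reported as NaN) when a log argument is non-positive or no site
is comparable.

**Discrimination (Pm).** A sample is identified when every member of its
nearest-neighbour set — all non-self samples at the minimum defined K2P
distance — is conspecific (ties containing a heterospecific sample fail;
a permissive `tie_rule="any"` is available). Pm is the percentage of
samples identified; a species succeeds only if all its samples do.

**Nucleotide diversity.** π is the mean over unordered sequence pairs of
(differing sites / comparable sites), with pairwise deletion of gapped or
ambiguous positions.

**Mini-barcode search.** Window lengths 50, 60, 70, … bp are scanned at
every column offset; the first length whose best window matches the
full-length discriminated-sample *count* (an integer comparison, immune to
percentage rounding) is the shortest mini-barcode.

## Worked example

Everything is testable offline via the seeded simulators, which plant a
known truth (substitutions with transition bias κ, indels, hairpin
microinversions; multi-species marker panels with a barcode gap):

```python
import minibarcode as mb

pair, features, truth = mb.simulate_genome_pair(seed=7)   # 50 kb pair
events, summary = mb.classify_substitutions(pair, features)
indels, hist = mb.detect_indels(pair, features)
inversions = mb.detect_inversions(pair)
print(f"substitutions: {summary.n_total} (Ts {summary.n_transition}, "
      f"Tv {summary.n_transversion}, Ts/Tv {summary.ts_tv:.2f})")
print("inversion loops:", [(i.loop_start, i.loop_length, i.stem_length)
                           for i in inversions])

aln, species, _ = mb.simulate_marker_dataset(
    mb.MarkerParams(n_species=8, n_per_species=3,
                    between_divergence=0.02, within_divergence=0.001),
    seed=7)
result = mb.shortest_minibarcode(aln, species)
print(f"full-length Pm: {result.full_length_pm:.2f}%")
print(f"shortest mini-barcode: {result.shortest_length} bp at columns "
      f"{result.best_window_start + 1}-"
      f"{result.best_window_start + result.shortest_length}")
```

prints

```
substitutions: 150 (Ts 86, Tv 64, Ts/Tv 1.34)
inversion loops: [(26712, 14, 7), (31605, 14, 11), (32415, 19, 13)]
full-length Pm: 100.00%
shortest mini-barcode: 50 bp at columns 111-160
```

i.e. all 150 planted substitutions are recovered with the planted
transition bias, the three planted inversion loops are found at their exact
positions and lengths, the 8-species × 3-sample panel (between-species
divergence 20× the within-species divergence) is fully discriminated at
full length, and a 50 bp window already retains that 100% discrimination.

The same stages are available as CLI verbs:

```sh
minibarcode simulate genome-pair --seed 7 --out sim
minibarcode compare-genomes --pair sim/pair.fasta --features sim/features.tsv --out cmp
minibarcode scan-diversity --alignment sim/pair.fasta --window 600 --step 25 --out cmp
minibarcode evaluate-barcode --alignment marker.fasta --species map.tsv
minibarcode find-minibarcode --alignment marker.fasta --species map.tsv --start 50 --increment 10
minibarcode run --config run.yaml        # full pipeline + manifest.json
```

Every output TSV/JSON carries a header naming the tool version and
parameters; file coordinates are 1-based inclusive.

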