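"""Seeded generators for genome pairs and multi-species marker alignments
with fully known planted truth.

The genome-pair generator emulates a pair of closely related plastomes
(~0.3% divergent by default): point substitutions with a transition bias
kappa, indels as gap runs, and microinversions planted as
reverse-complemented hairpin loops flanked by inverted repeats. Events are
placed by rejection sampling into non-overlapping positions separated by at
least two matching columns, so every planted event is recoverable exactly.

The marker generator emulates a multi-species resequencing panel on a star
phylogeny: a per-species consensus mutated from a common ancestor at the
between-species divergence (optionally confined to a diagnostic block),
then individuals mutated from their consensus at the within-species
divergence. No indels are introduced in marker mode, keeping distance
oracles closed-form.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    AlignedPair,
    FeatureTable,
    Interval,
    MarkerAlignment,
    SequenceRecord,
    SpeciesMap,
)
from .genome_comparison import _COMPLEMENT, is_transition

BASES = np.array(list("ACGT"))
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION_PARTNERS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}

# Default transition bias: Ts fraction kappa/(kappa+2) ≈ 0.59, the bias
# typical of plastome comparisons between congeners.
DEFAULT_KAPPA = 2.86


@dataclass
class GenomePairParams:
    length: int = 50_000
    n_substitutions: int = 150
    n_indels: int = 50
    n_inversions: int = 3
    kappa: float = DEFAULT_KAPPA
    p_single_bp_indel: float = 0.63
    max_indel_length: int = 34
    loop_length_range: tuple[int, int] = (14, 19)
    stem_length_range: tuple[int, int] = (5, 12)
    coding_interval: int = 1000
    spacer_interval: int = 500


@dataclass
class GenomePairTruth:
    seed: int
    length: int
    kappa: float
    substitutions: list[tuple[int, str, str]]  # (ref_pos, ref_base, other_base)
    indels: list[tuple[int, int, str]]  # (ref_pos, length, carrier)
    inversions: list[tuple[int, int, int]]  # (loop_start, loop_length, stem_length)

    @property
    def n_transitions(self) -> int:
        return sum(is_transition(r, o) for _, r, o in self.substitutions)


@dataclass
class MarkerParams:
    n_species: int = 8
    n_per_species: int = 3
    length: int = 800
    between_divergence: float = 0.02
    within_divergence: float = 0.001
    kappa: float = DEFAULT_KAPPA
    diagnostic_block: tuple[int, int] | None = None  # (start, length)


@dataclass
class MarkerTruth:
    seed: int
    n_species: int
    n_per_species: int
    between_divergence: float
    within_divergence: float
    kappa: float
    diagnostic_block: tuple[int, int] | None = None


def _mutate_base(base: str, kappa: float, rng: np.random.Generator) -> str:
    if rng.random() < kappa / (kappa + 2.0):
        return _TRANSITION_PARTNER[base]
    return _TRANSVERSION_PARTNERS[base][rng.integers(2)]


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mismatching_loop(length: int, rng: np.random.Generator) -> str:
    """A loop sequence whose reverse complement differs from it at every
    position, so the planted inversion reads as one full mismatch run."""
    loop = [""] * length
    for i in range(length // 2):
        j = length - 1 - i
        loop[i] = str(BASES[rng.integers(0, 4)])
        forbidden = _COMPLEMENT[loop[i]]
        choices = [b for b in "ACGT" if b != forbidden]
        loop[j] = choices[rng.integers(3)]
    if length % 2 == 1:
        loop[length // 2] = str(BASES[rng.integers(0, 4)])  # base != own complement
    return "".join(loop)


def _place_events(
    sizes: list[int], length: int, rng: np.random.Generator, margin: int = 2
) -> list[int]:
    """Rejection-sample non-overlapping start positions (margin columns apart)."""
    if sum(s + 2 * margin for s in sizes) > length - 2:
        raise ValueError("requested events cannot be packed into the sequence")
    placed: list[tuple[int, int]] = []  # (start, end) with margin
    starts: list[int] = []
    for size in sizes:
        for _ in range(20_000):
            start = int(rng.integers(1, length - size - 1))
            lo, hi = start - margin, start + size + margin
            if all(hi <= s or lo >= e for s, e in placed):
                placed.append((lo, hi))
                starts.append(start)
                break
        else:
            raise ValueError("could not place events without overlap; too dense")
    return starts


def simulate_genome_pair(
    params: GenomePairParams | None = None, seed: int = 0
) -> tuple[AlignedPair, FeatureTable, GenomePairTruth]:
    """Generate an aligned genome pair with planted, non-overlapping events.

    Identical seeds reproduce byte-identical output.
    """
    p = params or GenomePairParams()
    rng = np.random.default_rng(seed)
    ref = list(_random_sequence(p.length, rng))

    # event footprints on the ungapped reference
    inv_specs = []
    for _ in range(p.n_inversions):
        loop = int(rng.integers(p.loop_length_range[0], p.loop_length_range[1] + 1))
        stem = int(rng.integers(p.stem_length_range[0], p.stem_length_range[1] + 1))
        inv_specs.append((loop, stem))
    indel_lengths = []
    for _ in range(p.n_indels):
        if rng.random() < p.p_single_bp_indel:
            indel_lengths.append(1)
        else:
            ln = 2 + int(rng.geometric(0.25))
            indel_lengths.append(min(ln, p.max_indel_length))
    indel_carriers = ["reference" if rng.random() < 0.5 else "other"
                      for _ in range(p.n_indels)]

    sizes = (
        [1] * p.n_substitutions
        + [l if c == "other" else 1 for l, c in zip(indel_lengths, indel_carriers)]
        + [loop + 2 * stem for loop, stem in inv_specs]
    )
    starts = _place_events(sizes, p.length, rng)
    sub_starts = starts[: p.n_substitutions]
    indel_starts = starts[p.n_substitutions : p.n_substitutions + p.n_indels]
    inv_starts = starts[p.n_substitutions + p.n_indels :]

    substitutions: list[tuple[int, str, str]] = []
    # other-genome base overrides and structural edits keyed by ref position
    overrides: dict[int, str] = {}
    for pos in sub_starts:
        ref_base = ref[pos]
        other_base = _mutate_base(ref_base, p.kappa, rng)
        overrides[pos] = other_base
        substitutions.append((pos, ref_base, other_base))

    deletions: dict[int, int] = {}  # gap in other: ref positions [pos, pos+len)
    insertions: dict[int, tuple[str, int]] = {}  # gap in ref after pos: other bases
    indels: list[tuple[int, int, str]] = []
    for pos, ln, carrier in zip(indel_starts, indel_lengths, indel_carriers):
        if carrier == "other":
            deletions[pos] = ln
            indels.append((pos - 1, ln, carrier))
        else:
            insertions[pos] = (_random_sequence(ln, rng), ln)
            indels.append((pos, ln, carrier))

    inversions: list[tuple[int, int, int]] = []
    inverted_loops: dict[int, tuple[str, str, int]] = {}
    for pos, (loop_len, stem_len) in zip(inv_starts, inv_specs):
        stem = _random_sequence(stem_len, rng)
        loop = _mismatching_loop(loop_len, rng)
        rc_stem = "".join(_COMPLEMENT[b] for b in reversed(stem))
        rc_loop = "".join(_COMPLEMENT[b] for b in reversed(loop))
        segment = stem + loop + rc_stem
        for k, b in enumerate(segment):
            ref[pos + k] = b
        loop_start = pos + stem_len
        inverted_loops[loop_start] = (loop, rc_loop, loop_len)
        inversions.append((loop_start, loop_len, stem_len))

    # assemble the aligned pair column by column
    ref_cols: list[str] = []
    oth_cols: list[str] = []
    i = 0
    while i < p.length:
        if i in inverted_loops:
            loop, rc_loop, ln = inverted_loops[i]
            ref_cols.append(loop)
            oth_cols.append(rc_loop)
            i += ln
            continue
        if i in deletions:
            ln = deletions[i]
            ref_cols.append("".join(ref[i : i + ln]))
            oth_cols.append("-" * ln)
            i += ln
            continue
        ref_cols.append(ref[i])
        oth_cols.append(overrides.get(i, ref[i]))
        if i in insertions:
            bases, ln = insertions[i]
            ref_cols.append("-" * ln)
            oth_cols.append(bases)
        i += 1

    pair = AlignedPair(
        SequenceRecord("reference_genome", "".join(ref_cols)),
        SequenceRecord("other_genome", "".join(oth_cols)),
    )
    intervals: list[Interval] = []
    pos = 0
    gene_no = 1
    while pos < p.length:
        end = min(pos + p.coding_interval, p.length)
        if end > pos:
            intervals.append(Interval(pos, end, "coding", f"gene{gene_no}"))
            gene_no += 1
        pos = end + p.spacer_interval
    truth = GenomePairTruth(
        seed=seed,
        length=p.length,
        kappa=p.kappa,
        substitutions=sorted(substitutions),
        indels=sorted(indels),
        inversions=sorted(inversions),
    )
    return pair, FeatureTable(intervals), truth


def simulate_marker_dataset(
    params: MarkerParams | None = None, seed: int = 0
) -> tuple[MarkerAlignment, SpeciesMap, MarkerTruth]:
    """Generate a star-phylogeny marker panel with a known barcode gap."""
    p = params or MarkerParams()
    if p.n_species < 2 or p.n_per_species < 1:
        raise ValueError("need >= 2 species and >= 1 sample per species")
    for rate in (p.between_divergence, p.within_divergence):
        if not (0.0 <= rate <= 0.75):
            raise ValueError("divergence rates must lie in [0, 0.75]")
    if p.within_divergence > p.between_divergence:
        raise ValueError("within-species divergence exceeds between-species divergence")
    rng = np.random.default_rng(seed)
    ancestor = _random_sequence(p.length, rng)

    if p.diagnostic_block is not None:
        b_start, b_len = p.diagnostic_block
        if not (0 <= b_start and b_start + b_len <= p.length):
            raise ValueError("diagnostic block outside the alignment")
        block = set(range(b_start, b_start + b_len))
    else:
        block = None

    def mutate(seq: str, rate: float, restrict: set[int] | None) -> str:
        out = list(seq)
        for i in range(len(out)):
            if restrict is not None and i not in restrict:
                continue
            if rng.random() < rate:
                out[i] = _mutate_base(out[i], p.kappa, rng)
        return "".join(out)

    records: list[SequenceRecord] = []
    mapping: dict[str, str] = {}
    for si in range(p.n_species):
        species = f"species_{si + 1:02d}"
        consensus = mutate(ancestor, p.between_divergence, block)
        for k in range(p.n_per_species):
            sample = f"sp{si + 1:02d}_{k + 1:02d}"
            residues = mutate(consensus, p.within_divergence, None)
            records.append(SequenceRecord(sample, residues, species))
            mapping[sample] = species
    aln = MarkerAlignment(records, marker_name="synthetic_marker")
    truth = MarkerTruth(
        seed=seed,
        n_species=p.n_species,
        n_per_species=p.n_per_species,
        between_divergence=p.between_divergence,
        within_divergence=p.within_divergence,
        kappa=p.kappa,
        diagnostic_block=p.diagnostic_block,
    )
    return aln, SpeciesMap(mapping), truth


def truth_to_json(truth, path: str | Path) -> None:
    """Serialise a truth record (dataclass) to JSON."""
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2)
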