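"""Shared data model and readers/writers for aligned FASTA, species maps and
feature tables.

All coordinates are 0-based half-open internally; files and human-readable
reports use 1-based inclusive coordinates. Sequences are upper-cased on input
and any symbol outside {A, C, G, T} (IUPAC ambiguity codes, N, gaps) is
treated as missing data by every downstream analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("minibarcode")

GAP = "-"
UNAMBIGUOUS = frozenset("ACGT")
FEATURE_CATEGORIES = ("coding", "intron", "spacer", "rRNA", "tRNA")

__all__ = [
    "GAP",
    "UNAMBIGUOUS",
    "FEATURE_CATEGORIES",
    "SequenceRecord",
    "MarkerAlignment",
    "AlignedPair",
    "Interval",
    "FeatureTable",
    "SpeciesMap",
    "FormatError",
    "read_alignment",
    "write_alignment",
    "read_species_map",
    "write_species_map",
    "read_feature_table",
    "drop_shared_gap_columns",
    "gapped_to_ungapped",
    "ungapped_to_gapped",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """One (possibly gapped) sequence with its sample identifier.

    ``species`` may be empty for whole-genome records.
    """

    sample_id: str
    residues: str
    species: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count(GAP)

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


class MarkerAlignment:
    """A multi-sample gapped alignment of one marker region."""

    def __init__(self, records: Sequence[SequenceRecord], marker_name: str = ""):
        records = list(records)
        if not records:
            raise FormatError("alignment has no records")
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            raise FormatError(f"records have unequal lengths: {sorted(lengths)}")
        if len(records[0]) < 1:
            raise FormatError("alignment has zero columns")
        ids = [r.sample_id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sample ids in alignment: {dup}")
        self.records = records
        self.marker_name = marker_name

    @property
    def n_samples(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def to_matrix(self) -> np.ndarray:
        """Return the alignment as an (n_samples, n_columns) byte matrix."""
        return np.frombuffer(
            "".join(r.residues for r in self.records).encode("ascii"), dtype="S1"
        ).reshape(self.n_samples, self.length)

    def slice_columns(self, start: int, stop: int) -> "MarkerAlignment":
        return MarkerAlignment(
            [
                SequenceRecord(r.sample_id, r.residues[start:stop], r.species)
                for r in self.records
            ],
            marker_name=self.marker_name,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MarkerAlignment({self.marker_name or '<unnamed>'}, "
            f"{self.n_samples} samples x {self.length} columns)"
        )


class AlignedPair:
    """Two genome sequences gapped to identical length, one designated the
    reference.

    Columns gapped in both sequences are dropped at construction so that
    every remaining gap column belongs to exactly one sequence.
    """

    def __init__(self, reference: SequenceRecord, other: SequenceRecord):
        if len(reference) != len(other):
            raise FormatError(
                f"pair records have unequal lengths: {len(reference)} vs {len(other)}"
            )
        ref_res, other_res, dropped = drop_shared_gap_columns(
            reference.residues, other.residues
        )
        if dropped:
            logger.info("dropped %d shared-gap columns at load", dropped)
        self.reference = SequenceRecord(reference.sample_id, ref_res, reference.species)
        self.other = SequenceRecord(other.sample_id, other_res, other.species)
        self.n_dropped_columns = dropped

    @property
    def length(self) -> int:
        return len(self.reference)

    def to_alignment(self, marker_name: str = "") -> MarkerAlignment:
        return MarkerAlignment([self.reference, self.other], marker_name=marker_name)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"AlignedPair({self.reference.sample_id} vs {self.other.sample_id}, "
            f"{self.length} columns)"
        )


def drop_shared_gap_columns(a: str, b: str) -> tuple[str, str, int]:
    """Remove columns gapped in both sequences; returns (a, b, n_dropped)."""
    if len(a) != len(b):
        raise FormatError("sequences have unequal lengths")
    keep = [i for i in range(len(a)) if not (a[i] == GAP and b[i] == GAP)]
    dropped = len(a) - len(keep)
    if dropped == 0:
        return a, b, 0
    return "".join(a[i] for i in keep), "".join(b[i] for i in keep), dropped


def gapped_to_ungapped(residues: str) -> dict[int, int]:
    """Map gapped column index -> ungapped position, for non-gap columns only."""
    out: dict[int, int] = {}
    pos = 0
    for i, c in enumerate(residues):
        if c != GAP:
            out[i] = pos
            pos += 1
    return out


def ungapped_to_gapped(residues: str) -> dict[int, int]:
    """Inverse of :func:`gapped_to_ungapped`."""
    return {v: k for k, v in gapped_to_ungapped(residues).items()}


@dataclass(frozen=True)
class Interval:
    start: int
    end: int
    category: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.category not in FEATURE_CATEGORIES:
            raise FormatError(
                f"unknown feature category {self.category!r}; "
                f"expected one of {FEATURE_CATEGORIES}"
            )
        if not (0 <= self.start < self.end):
            raise FormatError(f"bad interval [{self.start}, {self.end})")


class FeatureTable:
    """Annotated intervals on the ungapped reference, 0-based half-open.

    Intervals within one category must not overlap; intervals of different
    categories may (a gene and the spacer flanking it are distinct layers).
    """

    def __init__(self, intervals: Iterable[Interval]):
        self.intervals = sorted(intervals, key=lambda iv: (iv.start, iv.end))
        by_cat: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            by_cat.setdefault(iv.category, []).append(iv)
        for cat, ivs in by_cat.items():
            for prev, cur in zip(ivs, ivs[1:]):
                if cur.start < prev.end:
                    raise FormatError(
                        f"overlapping {cat} intervals: "
                        f"{prev.name or prev.start}..{prev.end} and "
                        f"{cur.name or cur.start}..{cur.end}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def validate_against_length(self, reference_length: int) -> None:
        for iv in self.intervals:
            if iv.end > reference_length:
                raise FormatError(
                    f"interval {iv.name or ''}[{iv.start},{iv.end}) exceeds "
                    f"reference length {reference_length}"
                )

    def counts_by_category(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for iv in self.intervals:
            out[iv.category] = out.get(iv.category, 0) + 1
        return out


@dataclass
class SpeciesMap:
    """sample_id -> species lookup."""

    mapping: dict[str, str] = field(default_factory=dict)

    def species_of(self, sample_id: str) -> str:
        try:
            return self.mapping[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} absent from species map") from None

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp in self.mapping.values():
            seen.setdefault(sp)
        return list(seen)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, sp in self.mapping.items():
            out.setdefault(sp, []).append(sample)
        return out

    def labels_for(self, sample_ids: Sequence[str]) -> list[str]:
        return [self.species_of(s) for s in sample_ids]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_alignment(
    path: str | Path,
    kind: str = "marker",
    reference_id: str | None = None,
    marker_name: str | None = None,
):
    """Read an aligned FASTA file.

    kind="marker" returns a :class:`MarkerAlignment`; kind="genome-pair"
    requires exactly two records and returns an :class:`AlignedPair` whose
    reference is the record named by ``reference_id`` (default: first record).
    """
    path = Path(path)
    records = [
        SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    if kind == "marker":
        recs, dropped = _drop_shared_gaps_multi(records)
        if dropped:
            logger.info("%s: dropped %d all-gap columns", path.name, dropped)
        return MarkerAlignment(recs, marker_name=marker_name or path.stem)
    if kind == "genome-pair":
        if len(records) != 2:
            raise FormatError(
                f"{path}: genome-pair requires exactly 2 records, found {len(records)}"
            )
        ref, other = records
        if reference_id is not None:
            if ref.sample_id != reference_id:
                if other.sample_id != reference_id:
                    raise FormatError(
                        f"{path}: reference id {reference_id!r} not present"
                    )
                ref, other = other, ref
        return AlignedPair(ref, other)
    raise ValueError(f"unknown kind {kind!r}")


def _drop_shared_gaps_multi(
    records: list[SequenceRecord],
) -> tuple[list[SequenceRecord], int]:
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise FormatError(f"records have unequal lengths: {sorted(lengths)}")
    mat = np.frombuffer(
        "".join(r.residues for r in records).encode("ascii"), dtype="S1"
    ).reshape(len(records), -1)
    all_gap = (mat == GAP.encode()).all(axis=0)
    dropped = int(all_gap.sum())
    if dropped == 0:
        return records, 0
    keep = ~all_gap
    out = [
        SequenceRecord(r.sample_id, mat[i, keep].tobytes().decode("ascii"), r.species)
        for i, r in enumerate(records)
    ]
    return out, dropped


def write_alignment(aln: MarkerAlignment | AlignedPair, path: str | Path) -> None:
    if isinstance(aln, AlignedPair):
        aln = aln.to_alignment()
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.sample_id, description="")
        for r in aln.records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_species_map(path: str | Path) -> SpeciesMap:
    """Read a two-column TSV (sample_id<TAB>species) with a header row."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty species map")
    for ln in lines[1:]:  # first non-comment line is the header
        parts = ln.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}: expected 2 tab-separated columns: {ln!r}")
        sample, species = parts[0].strip(), parts[1].strip()
        if sample in mapping:
            raise FormatError(f"{path}: duplicate sample_id {sample!r}")
        mapping[sample] = species
    return SpeciesMap(mapping)


def write_species_map(species_map: SpeciesMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tspecies\n")
        for sample, sp in species_map.mapping.items():
            fh.write(f"{sample}\t{sp}\n")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature table: TSV columns start, end, category, name.

    Coordinates in the file are 1-based inclusive (GFF convention) and are
    converted to 0-based half-open internally.
    """
    path = Path(path)
    intervals: list[Interval] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty feature table")
    start_idx = 0
    first = lines[0].split("\t")
    if first and not first[0].isdigit():  # header row
        start_idx = 1
    for ln in lines[start_idx:]:
        parts = ln.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: expected >=3 columns: {ln!r}")
        start_1, end_1 = int(parts[0]), int(parts[1])
        name = parts[3].strip() if len(parts) > 3 else ""
        intervals.append(Interval(start_1 - 1, end_1, parts[2].strip(), name))
    return FeatureTable(intervals)
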