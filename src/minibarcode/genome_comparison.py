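"""Pairwise comparison of two aligned congeneric plastomes.

Characterises the differences between a reference genome and a close
relative: point substitutions (with the strand-collapsed six-type spectrum
and transition/transversion ratios stratified by annotation region), indel
events (maximal single-sequence gap runs), and short inversions that sit in
the loop of a hairpin whose stem is a flanking inverted repeat.

Indel polarity (insertion vs deletion) is not assignable without an
outgroup; events record only which sequence carries the gap, and report
writers phrase polarity relative to the designated reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core_io import (
    GAP,
    UNAMBIGUOUS,
    AlignedPair,
    FeatureTable,
    gapped_to_ungapped,
)

logger = logging.getLogger("minibarcode")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Strand-collapsed substitution classes: each unordered strand pair
# {(ref, other), (comp ref, comp other)} has exactly one representative here.
COLLAPSED_TYPES = ("C→T", "T→C", "C→A", "A→C", "C→G", "A→T")
_COLLAPSE = {
    ("C", "T"): "C→T", ("G", "A"): "C→T",
    ("T", "C"): "T→C", ("A", "G"): "T→C",
    ("C", "A"): "C→A", ("G", "T"): "C→A",
    ("A", "C"): "A→C", ("T", "G"): "A→C",
    ("C", "G"): "C→G", ("G", "C"): "C→G",
    ("A", "T"): "A→T", ("T", "A"): "A→T",
}

REGION_CATEGORIES = ("coding", "intron", "spacer", "rRNA", "tRNA", "unannotated")


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def is_transition(a: str, b: str) -> bool:
    pair = {a, b}
    return pair <= PURINES or pair <= PYRIMIDINES


@dataclass(frozen=True)
class SubstitutionEvent:
    ref_pos: int  # ungapped reference coordinate
    ref_base: str
    other_base: str
    collapsed_type: str
    transition: bool
    region_category: str


@dataclass
class SubstitutionSummary:
    n_total: int
    n_transition: int
    n_transversion: int
    spectrum: dict[str, int]
    by_region: dict[str, dict[str, int]]  # region -> {"ts": n, "tv": n}

    @property
    def ts_tv(self) -> float | None:
        if self.n_transversion == 0:
            return None
        return self.n_transition / self.n_transversion


@dataclass(frozen=True)
class IndelEvent:
    ref_pos: int  # ungapped ref position of the column preceding the gap run
    length: int
    carrier: str  # "reference" | "other" — which sequence holds the gap
    region_category: str = "unannotated"


@dataclass(frozen=True)
class InversionEvent:
    loop_start: int  # ungapped reference coordinates, half-open
    loop_end: int
    loop_length: int
    stem_length: int
    stem_sequences: tuple[str, str] = ("", "")


def region_of(ref_pos: int, features: FeatureTable | None, reference_length: int) -> str:
    """Annotation category of an ungapped reference position.

    Positions covered by no interval are called "spacer" when they lie
    between annotated features and "unannotated" when they fall before the
    first or after the last feature (or when no annotation exists at all).
    """
    if not (0 <= ref_pos < reference_length):
        raise IndexError(f"position {ref_pos} outside reference [0, {reference_length})")
    if features is None or len(features) == 0:
        return "unannotated"
    has_before = has_after = False
    for iv in features:
        if iv.start <= ref_pos < iv.end:
            return iv.category
        if iv.end <= ref_pos:
            has_before = True
        if iv.start > ref_pos:
            has_after = True
    return "spacer" if (has_before and has_after) else "unannotated"


def classify_substitutions(
    pair: AlignedPair,
    features: FeatureTable | None = None,
    mask_inversions: bool = True,
    inversions: list[InversionEvent] | None = None,
) -> tuple[list[SubstitutionEvent], SubstitutionSummary]:
    """List every point substitution and summarise the spectrum.

    A substitution is a column where both sequences carry an unambiguous base
    and the bases differ. Columns inside accepted inversion loops are
    excluded by default, since a reverse-complemented segment read
    column-by-column would inflate the substitution spectrum.
    """
    ref_len = pair.reference.ungapped_length
    if features is not None:
        features.validate_against_length(ref_len)
    masked: set[int] = set()
    if mask_inversions:
        if inversions is None:
            inversions = detect_inversions(pair)
        for inv in inversions:
            masked.update(range(inv.loop_start, inv.loop_end))

    col_to_refpos = gapped_to_ungapped(pair.reference.residues)
    events: list[SubstitutionEvent] = []
    for col, (a, b) in enumerate(zip(pair.reference.residues, pair.other.residues)):
        if a == b or a not in UNAMBIGUOUS or b not in UNAMBIGUOUS:
            continue
        pos = col_to_refpos[col]
        if pos in masked:
            continue
        events.append(
            SubstitutionEvent(
                ref_pos=pos,
                ref_base=a,
                other_base=b,
                collapsed_type=_COLLAPSE[(a, b)],
                transition=is_transition(a, b),
                region_category=region_of(pos, features, ref_len),
            )
        )

    spectrum = {t: 0 for t in COLLAPSED_TYPES}
    by_region: dict[str, dict[str, int]] = {}
    n_ts = 0
    for ev in events:
        spectrum[ev.collapsed_type] += 1
        reg = by_region.setdefault(ev.region_category, {"ts": 0, "tv": 0})
        if ev.transition:
            n_ts += 1
            reg["ts"] += 1
        else:
            reg["tv"] += 1
    summary = SubstitutionSummary(
        n_total=len(events),
        n_transition=n_ts,
        n_transversion=len(events) - n_ts,
        spectrum=spectrum,
        by_region=by_region,
    )
    return events, summary


def tstv_by_region(summary: SubstitutionSummary) -> pd.DataFrame:
    """Per-region transition/transversion table; ratio None when n_tv = 0."""
    rows = []
    for region, counts in sorted(summary.by_region.items()):
        ts, tv = counts["ts"], counts["tv"]
        rows.append(
            {
                "region": region,
                "n_ts": ts,
                "n_tv": tv,
                "ts_tv": round(ts / tv, 2) if tv > 0 else None,
            }
        )
    return pd.DataFrame(rows, columns=["region", "n_ts", "n_tv", "ts_tv"])


def detect_indels(
    pair: AlignedPair, features: FeatureTable | None = None
) -> tuple[list[IndelEvent], dict[str, int]]:
    """One event per maximal single-sequence gap run, plus a length histogram.

    Terminal gap runs are treated as missing sequence ends, not indels, and
    are logged. Histogram bins are lengths 1..10 plus a ">10" tail.
    """
    ref_len = pair.reference.ungapped_length
    if features is not None:
        features.validate_against_length(ref_len)
    col_to_refpos = gapped_to_ungapped(pair.reference.residues)
    events: list[IndelEvent] = []
    n_terminal = 0
    L = pair.length
    for carrier, seq in (("reference", pair.reference.residues),
                         ("other", pair.other.residues)):
        col = 0
        while col < L:
            if seq[col] != GAP:
                col += 1
                continue
            run_start = col
            while col < L and seq[col] == GAP:
                col += 1
            if run_start == 0 or col == L:
                n_terminal += 1
                continue
            # ungapped ref position of the last reference base before the run
            prev_col = run_start - 1
            while prev_col >= 0 and prev_col not in col_to_refpos:
                prev_col -= 1
            ref_pos = col_to_refpos[prev_col] if prev_col >= 0 else 0
            events.append(
                IndelEvent(
                    ref_pos=ref_pos,
                    length=col - run_start,
                    carrier=carrier,
                    region_category=region_of(ref_pos, features, ref_len),
                )
            )
    if n_terminal:
        logger.info("excluded %d terminal gap runs as missing ends", n_terminal)
    events.sort(key=lambda e: (e.ref_pos, e.carrier))

    histogram = {str(i): 0 for i in range(1, 11)}
    histogram[">10"] = 0
    for ev in events:
        key = str(ev.length) if ev.length <= 10 else ">10"
        histogram[key] += 1
    return events, histogram


def detect_inversions(
    pair: AlignedPair,
    min_loop: int = 5,
    max_loop: int = 60,
    max_loop_mismatch: int = 0,
    min_stem: int = 3,
    max_stem_scan: int = 60,
) -> list[InversionEvent]:
    """Find short reverse-complemented segments with a hairpin structure.

    Candidates are maximal runs of >= ``min_loop`` consecutive columns that
    mismatch (or are gapped) between the sequences. A candidate is accepted
    when the reverse complement of the reference segment equals the other
    segment within ``max_loop_mismatch`` differences. The hairpin stem is the
    inverted repeat flanking the loop in the reference, grown by greedy
    outward extension and reported only when >= ``min_stem``.
    """
    ref = pair.reference.residues
    oth = pair.other.residues
    L = pair.length
    col_to_refpos = gapped_to_ungapped(ref)
    ref_ungapped = pair.reference.ungapped()

    def col_differs(i: int) -> bool:
        a, b = ref[i], oth[i]
        if a == GAP or b == GAP:
            return True
        if a in UNAMBIGUOUS and b in UNAMBIGUOUS:
            return a != b
        return False  # ambiguity = missing, not evidence of inversion

    events: list[InversionEvent] = []
    col = 0
    while col < L:
        if not col_differs(col):
            col += 1
            continue
        run_start = col
        while col < L and col_differs(col):
            col += 1
        run_len = col - run_start
        if run_len < min_loop or run_len > max_loop:
            continue
        ref_seg = "".join(c for c in ref[run_start:col] if c != GAP)
        oth_seg = "".join(c for c in oth[run_start:col] if c != GAP)
        if len(ref_seg) != len(oth_seg) or len(ref_seg) < min_loop:
            continue
        if any(c not in UNAMBIGUOUS for c in ref_seg + oth_seg):
            continue
        mismatches = sum(
            a != b for a, b in zip(reverse_complement(ref_seg), oth_seg)
        )
        if mismatches > max_loop_mismatch:
            continue
        # loop span in ungapped reference coordinates
        loop_cols = [i for i in range(run_start, col) if i in col_to_refpos]
        if not loop_cols:
            continue
        loop_start = col_to_refpos[loop_cols[0]]
        loop_end = col_to_refpos[loop_cols[-1]] + 1
        # greedy outward stem extension on the ungapped reference
        stem = 0
        while (
            stem < max_stem_scan
            and loop_start - 1 - stem >= 0
            and loop_end + stem < len(ref_ungapped)
        ):
            left = ref_ungapped[loop_start - 1 - stem]
            right = ref_ungapped[loop_end + stem]
            if (
                left in UNAMBIGUOUS
                and right in UNAMBIGUOUS
                and right == _COMPLEMENT[left]
            ):
                stem += 1
            else:
                break
        if stem < min_stem:
            continue
        events.append(
            InversionEvent(
                loop_start=loop_start,
                loop_end=loop_end,
                loop_length=len(ref_seg),
                stem_length=stem,
                stem_sequences=(
                    ref_ungapped[loop_start - stem:loop_start],
                    ref_ungapped[loop_end:loop_end + stem],
                ),
            )
        )
    return events
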