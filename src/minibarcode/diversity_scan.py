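"""Nucleotide diversity: whole-alignment, sliding-window, hotspot calling,
and per-marker variability statistics.

π is the mean over all unordered sequence pairs of the proportion of
differing sites among pairwise-comparable sites (pairwise deletion). No
small-sample (n/(n−1)) correction is applied by default: with a two-genome
comparison the correction doubles π, which is not the scale used for
hotspot screening; the corrected estimator is available behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._pairwise import site_class_arrays
from .core_io import GAP, UNAMBIGUOUS, AlignedPair, MarkerAlignment

logger = logging.getLogger("minibarcode")

DEFAULT_WINDOW = 600
DEFAULT_STEP = 25
DEFAULT_HOTSPOT_THRESHOLD = 0.012


def _as_alignment(aln: MarkerAlignment | AlignedPair) -> MarkerAlignment:
    return aln.to_alignment() if isinstance(aln, AlignedPair) else aln


def nucleotide_diversity(
    aln: MarkerAlignment | AlignedPair,
    gap_mode: str = "pairwise",
    corrected: bool = False,
) -> float:
    """Average pairwise proportion of differing sites (π, substitutions/site).

    gap_mode="pairwise" compares, per pair, the columns unambiguous in both
    sequences; gap_mode="complete" first drops every column containing a gap
    or ambiguity in any sequence. Pairs with no comparable site are excluded;
    NaN is returned when every pair is excluded. ``corrected`` applies the
    n/(n−1) sample-size factor.
    """
    aln = _as_alignment(aln)
    n = aln.n_samples
    if n < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    mat = aln.to_matrix()
    if gap_mode == "complete":
        good_all = np.isin(mat, np.array([b"A", b"C", b"G", b"T"])).all(axis=0)
        mat = mat[:, good_all]
        if mat.shape[1] == 0:
            return math.nan
    elif gap_mode != "pairwise":
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    comp, ts, tv, _ = site_class_arrays(mat)
    n_comp = comp.sum(axis=1)
    n_diff = (ts | tv).sum(axis=1)
    usable = n_comp > 0
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("excluded %d pairs with no comparable site", n_excluded)
    if not usable.any():
        return math.nan
    pi = float((n_diff[usable] / n_comp[usable]).mean())
    if corrected:
        pi *= n / (n - 1)
    return pi


@dataclass
class WindowDiversityTrack:
    """Sliding-window π track over alignment columns."""

    window_length: int
    step: int
    table: pd.DataFrame  # columns: window_start, midpoint, n_sites_compared, pi


def sliding_pi(
    aln: MarkerAlignment | AlignedPair,
    window_length: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> WindowDiversityTrack:
    """Sliding-window nucleotide diversity over alignment columns.

    Gap columns count toward a window's span but not toward its compared
    sites. The last partial window is dropped; an alignment shorter than one
    window falls back to a single full-length window with a warning.
    """
    aln = _as_alignment(aln)
    L = aln.length
    if L < window_length:
        logger.warning(
            "alignment (%d columns) shorter than window (%d); using one "
            "full-length window", L, window_length,
        )
        window_length = L
    mat = aln.to_matrix()
    comp, ts, tv, _ = site_class_arrays(mat)
    diff = ts | tv
    # prefix sums over columns -> O(1) per-window pair counts
    comp_cs = np.concatenate(
        [np.zeros((comp.shape[0], 1), dtype=np.int64), comp.cumsum(axis=1)], axis=1
    )
    diff_cs = np.concatenate(
        [np.zeros((diff.shape[0], 1), dtype=np.int64), diff.cumsum(axis=1)], axis=1
    )
    rows = []
    for start in range(0, L - window_length + 1, step):
        stop = start + window_length
        n_comp = comp_cs[:, stop] - comp_cs[:, start]
        n_diff = diff_cs[:, stop] - diff_cs[:, start]
        usable = n_comp > 0
        pi = float((n_diff[usable] / n_comp[usable]).mean()) if usable.any() else math.nan
        rows.append(
            {
                "window_start": start,
                "midpoint": start + window_length // 2,
                "n_sites_compared": float(n_comp.mean()),
                "pi": pi,
            }
        )
    return WindowDiversityTrack(
        window_length=window_length, step=step, table=pd.DataFrame(rows)
    )


@dataclass(frozen=True)
class Hotspot:
    start: int  # alignment columns, half-open
    end: int
    peak_pi: float
    threshold: float


def find_hotspots(
    track: WindowDiversityTrack, threshold: float = DEFAULT_HOTSPOT_THRESHOLD
) -> list[Hotspot]:
    """Merge maximal runs of consecutive above-threshold windows.

    Each hotspot spans from the first window's start to the last window's
    end (start + window length).
    """
    if track.table.empty:
        raise ValueError("empty diversity track")
    out: list[Hotspot] = []
    run: list[tuple[int, float]] = []
    for row in track.table.itertuples():
        if not math.isnan(row.pi) and row.pi > threshold:
            run.append((row.window_start, row.pi))
        elif run:
            out.append(_close_run(run, track.window_length, threshold))
            run = []
    if run:
        out.append(_close_run(run, track.window_length, threshold))
    return out


def _close_run(
    run: list[tuple[int, float]], window_length: int, threshold: float
) -> Hotspot:
    return Hotspot(
        start=run[0][0],
        end=run[-1][0] + window_length,
        peak_pi=max(pi for _, pi in run),
        threshold=threshold,
    )


@dataclass
class MarkerStats:
    """Variability summary for one marker alignment (Length, variable and
    parsimony-informative sites with percentages, π, indel events,
    haplotypes)."""

    marker_name: str
    aligned_length: int
    n_samples: int
    n_variable_sites: int
    percent_variable: float
    n_parsimony_informative: int
    percent_parsimony_informative: float
    pi: float
    n_indel_events: int
    n_haplotypes: int


def marker_stats(aln: MarkerAlignment) -> MarkerStats:
    """Per-marker variability statistics.

    A variable site is a column with >= 2 distinct unambiguous bases; a
    parsimony-informative site additionally requires >= 2 of those bases to
    each occur in >= 2 samples. Haplotypes are distinct sequences after
    dropping every column containing any gap or ambiguity. Indel events are
    distinct (start, length) maximal gap runs.
    """
    if aln.n_samples < 2:
        raise ValueError("marker statistics need >= 2 sequences")
    mat = aln.to_matrix()
    n, L = mat.shape
    bases = np.array([b"A", b"C", b"G", b"T"])
    counts = np.stack([(mat == b).sum(axis=0) for b in bases])  # (4, L)
    n_states = (counts > 0).sum(axis=0)
    variable = n_states >= 2
    informative = variable & ((counts >= 2).sum(axis=0) >= 2)

    good_all = np.isin(mat, bases).all(axis=0)
    haplotypes = {mat[i, good_all].tobytes() for i in range(n)}

    indel_keys: set[tuple[int, int]] = set()
    gap = GAP.encode()
    for i in range(n):
        row = mat[i]
        col = 0
        while col < L:
            if row[col] != gap:
                col += 1
                continue
            start = col
            while col < L and row[col] == gap:
                col += 1
            indel_keys.add((start, col - start))

    return MarkerStats(
        marker_name=aln.marker_name,
        aligned_length=L,
        n_samples=n,
        n_variable_sites=int(variable.sum()),
        percent_variable=round(100 * variable.sum() / L, 2),
        n_parsimony_informative=int(informative.sum()),
        percent_parsimony_informative=round(100 * informative.sum() / L, 2),
        pi=nucleotide_diversity(aln),
        n_indel_events=len(indel_keys),
        n_haplotypes=len(haplotypes),
    )
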