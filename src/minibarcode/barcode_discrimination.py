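"""K2P distances, nearest-neighbour species discrimination, and the
shortest-mini-barcode search.

The discrimination rule: a sample is identified successfully when every
member of its nearest-neighbour set — all non-self samples at the minimum
defined K2P distance — is conspecific. Pm is the percentage of samples
identified; a species succeeds only when all of its samples do. The search
for the shortest mini-barcode slides windows of increasing length (start
50 bp, +10 bp per round, offset step 1 column) and stops at the first
length whose best window discriminates as many samples as the full-length
marker.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._pairwise import site_class_arrays
from .core_io import MarkerAlignment, SpeciesMap

logger = logging.getLogger("minibarcode")

DEFAULT_CURVE_LENGTHS = (50, 100, 150, 200, 250, 300, 350)


def k2p_from_proportions(p: float, q: float) -> float:
    """Kimura 2-parameter distance from transition (P) and transversion (Q)
    proportions: d = −½·ln(1−2P−Q) − ¼·ln(1−2Q); NaN outside the domain."""
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    if a <= 0.0 or b <= 0.0:
        return math.nan
    return -0.5 * math.log(a) - 0.25 * math.log(b)


def k2p_distance(a: str, b: str) -> float:
    """K2P distance between two equal-length gapped sequences.

    Compared sites are the columns unambiguous in both sequences; NaN when
    there are none or the distance is outside the estimator's domain.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    mat = np.frombuffer((a + b).upper().encode("ascii"), dtype="S1").reshape(2, -1)
    comp, ts, tv, _ = site_class_arrays(mat)
    n_comp = int(comp.sum())
    if n_comp == 0:
        return math.nan
    return k2p_from_proportions(int(ts.sum()) / n_comp, int(tv.sum()) / n_comp)


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix; NaN marks undefined entries."""

    sample_ids: list[str]
    values: np.ndarray  # (n, n) float, diagonal 0

    @property
    def n_undefined(self) -> int:
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def _matrix_from_counts(
    n: int, pairs: list[tuple[int, int]], n_ts, n_tv, n_comp
) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_comp > 0, n_ts / np.maximum(n_comp, 1), np.nan)
        q = np.where(n_comp > 0, n_tv / np.maximum(n_comp, 1), np.nan)
        a = 1.0 - 2.0 * p - q
        b = 1.0 - 2.0 * q
        d = np.where((a > 0) & (b > 0), -0.5 * np.log(np.maximum(a, 1e-300))
                     - 0.25 * np.log(np.maximum(b, 1e-300)), np.nan)
    out = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        out[i, j] = out[j, i] = d[k]
    return out


def k2p_matrix(aln: MarkerAlignment) -> DistanceMatrix:
    """Pairwise K2P distances for every unordered sample pair."""
    if aln.n_samples < 2:
        raise ValueError("distance matrix needs >= 2 sequences")
    mat = aln.to_matrix()
    comp, ts, tv, pairs = site_class_arrays(mat)
    values = _matrix_from_counts(
        aln.n_samples, pairs,
        ts.sum(axis=1).astype(float),
        tv.sum(axis=1).astype(float),
        comp.sum(axis=1).astype(float),
    )
    dm = DistanceMatrix(aln.sample_ids, values)
    if dm.n_undefined:
        logger.info("%d undefined K2P entries", dm.n_undefined)
    return dm


@dataclass
class SampleResult:
    sample_id: str
    species: str
    nearest: list[str]
    min_distance: float
    success: bool


@dataclass
class DiscriminationResult:
    samples: list[SampleResult]
    pm: float  # percent of samples discriminated
    per_species: dict[str, bool]

    @property
    def n_success(self) -> int:
        return sum(s.success for s in self.samples)


def _discriminate_square(
    dist: np.ndarray, labels: list[str], tie_rule: str
) -> tuple[int, list[tuple[list[int], float, bool]]]:
    """Success count + per-sample (nearest indices, min distance, success)."""
    n = dist.shape[0]
    details: list[tuple[list[int], float, bool]] = []
    n_success = 0
    for i in range(n):
        row = dist[i].copy()
        row[i] = np.nan
        if np.isnan(row).all():
            details.append(([], math.nan, False))
            continue
        m = np.nanmin(row)
        nearest = [j for j in range(n) if not np.isnan(row[j]) and row[j] == m]
        conspecific = [labels[j] == labels[i] for j in nearest]
        if tie_rule == "all":
            ok = bool(nearest) and all(conspecific)
        elif tie_rule == "any":
            ok = any(conspecific)
        else:
            raise ValueError(f"unknown tie_rule {tie_rule!r}")
        n_success += ok
        details.append((nearest, float(m), ok))
    return n_success, details


def near_neighbour(
    matrix: DistanceMatrix, species: SpeciesMap, tie_rule: str = "all"
) -> DiscriminationResult:
    """Nearest-neighbour discrimination over a K2P distance matrix.

    tie_rule="all" (default) requires every tied nearest neighbour to be
    conspecific; "any" accepts a tie that includes at least one conspecific.
    A sample with no defined non-self distance fails.
    """
    labels = species.labels_for(matrix.sample_ids)
    if len(set(labels)) < 2:
        raise ValueError("discrimination requires >= 2 species")
    n_success, details = _discriminate_square(matrix.values, labels, tie_rule)
    samples = [
        SampleResult(
            sample_id=sid,
            species=labels[i],
            nearest=[matrix.sample_ids[j] for j in details[i][0]],
            min_distance=details[i][1],
            success=details[i][2],
        )
        for i, sid in enumerate(matrix.sample_ids)
    ]
    per_species: dict[str, bool] = {}
    for s in samples:
        per_species[s.species] = per_species.get(s.species, True) and s.success
    pm = 100.0 * n_success / len(samples)
    return DiscriminationResult(samples=samples, pm=pm, per_species=per_species)


@dataclass
class WindowScan:
    window_length: int
    window_step: int
    starts: list[int]
    pms: list[float]
    success_counts: list[int]
    max_pm: float
    best_start: int
    best_count: int


class _WindowEngine:
    """Prefix-summed per-pair site counts for O(1) window distance matrices."""

    def __init__(self, aln: MarkerAlignment, species: SpeciesMap, tie_rule: str):
        self.n = aln.n_samples
        self.length = aln.length
        self.labels = species.labels_for(aln.sample_ids)
        if len(set(self.labels)) < 2:
            raise ValueError("discrimination requires >= 2 species")
        self.tie_rule = tie_rule
        mat = aln.to_matrix()
        comp, ts, tv, self.pairs = site_class_arrays(mat)
        zero = np.zeros((comp.shape[0], 1), dtype=np.int64)
        self.comp_cs = np.concatenate([zero, comp.cumsum(axis=1)], axis=1)
        self.ts_cs = np.concatenate([zero, ts.cumsum(axis=1)], axis=1)
        self.tv_cs = np.concatenate([zero, tv.cumsum(axis=1)], axis=1)

    def success_count(self, start: int, stop: int) -> int:
        n_comp = (self.comp_cs[:, stop] - self.comp_cs[:, start]).astype(float)
        n_ts = (self.ts_cs[:, stop] - self.ts_cs[:, start]).astype(float)
        n_tv = (self.tv_cs[:, stop] - self.tv_cs[:, start]).astype(float)
        dist = _matrix_from_counts(self.n, self.pairs, n_ts, n_tv, n_comp)
        count, _ = _discriminate_square(dist, self.labels, self.tie_rule)
        return count


def window_pm(
    aln: MarkerAlignment,
    species: SpeciesMap,
    window_length: int,
    window_step: int = 1,
    tie_rule: str = "all",
    _engine: _WindowEngine | None = None,
) -> WindowScan:
    """Pm for every window of ``window_length`` columns (offset step 1 by
    default); ties in the argmax break toward the smallest start."""
    if window_length > aln.length:
        raise ValueError(
            f"window ({window_length}) longer than alignment ({aln.length})"
        )
    eng = _engine or _WindowEngine(aln, species, tie_rule)
    n = eng.n
    starts, counts = [], []
    for s in range(0, aln.length - window_length + 1, window_step):
        starts.append(s)
        counts.append(eng.success_count(s, s + window_length))
    pms = [100.0 * c / n for c in counts]
    best_idx = int(np.argmax(counts))  # argmax takes the first maximum
    return WindowScan(
        window_length=window_length,
        window_step=window_step,
        starts=starts,
        pms=pms,
        success_counts=counts,
        max_pm=pms[best_idx],
        best_start=starts[best_idx],
        best_count=counts[best_idx],
    )


def pm_length_curve(
    aln: MarkerAlignment,
    species: SpeciesMap,
    lengths: tuple[int, ...] = DEFAULT_CURVE_LENGTHS,
    window_step: int = 1,
    tie_rule: str = "all",
) -> pd.DataFrame:
    """Maximum Pm attainable at each window length; longer-than-alignment
    lengths are skipped with a warning."""
    eng = _WindowEngine(aln, species, tie_rule)
    rows = []
    for length in lengths:
        if length > aln.length:
            logger.warning(
                "skipping curve length %d > aligned length %d", length, aln.length
            )
            continue
        scan = window_pm(aln, species, length, window_step, tie_rule, _engine=eng)
        rows.append({"length": length, "max_pm": scan.max_pm})
    return pd.DataFrame(rows, columns=["length", "max_pm"])


@dataclass
class MiniBarcodeResult:
    marker_name: str
    shortest_length: int
    best_window_start: int  # alignment column, 0-based
    pm_at_shortest: float
    full_length_pm: float
    curve: list[tuple[int, float]] = field(default_factory=list)


def shortest_minibarcode(
    aln: MarkerAlignment,
    species: SpeciesMap,
    start: int = 50,
    increment: int = 10,
    window_step: int = 1,
    tie_rule: str = "all",
) -> MiniBarcodeResult:
    """Shortest window length matching the full-length discrimination power.

    Lengths start, start+increment, ... are scanned; the first length whose
    best window discriminates the same number of samples as the full-length
    marker (integer count comparison, immune to percentage rounding) wins.
    """
    if aln.length < start:
        raise ValueError(f"alignment ({aln.length} columns) shorter than start length {start}")
    eng = _WindowEngine(aln, species, tie_rule)
    full_count = eng.success_count(0, aln.length)
    full_pm = 100.0 * full_count / eng.n
    curve: list[tuple[int, float]] = []
    length = start
    while length <= aln.length:
        scan = window_pm(aln, species, length, window_step, tie_rule, _engine=eng)
        curve.append((length, scan.max_pm))
        if scan.best_count == full_count:
            return MiniBarcodeResult(
                marker_name=aln.marker_name,
                shortest_length=length,
                best_window_start=scan.best_start,
                pm_at_shortest=scan.max_pm,
                full_length_pm=full_pm,
                curve=curve,
            )
        length += increment
    logger.warning("no scanned length reached full-length power; returning full length")
    return MiniBarcodeResult(
        marker_name=aln.marker_name,
        shortest_length=aln.length,
        best_window_start=0,
        pm_at_shortest=full_pm,
        full_length_pm=full_pm,
        curve=curve,
    )
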