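"""Independent brute-force oracles used to check the implementation.

Everything here is written as plainly as possible — per-column character
loops, exhaustive enumeration — and never calls into the package's
computation paths.
"""

from __future__ import annotations

import math

import numpy as np

ACGT = set("ACGT")
PURINES = {"A", "G"}


def classify_column(a: str, b: str) -> str:
    """'comp' comparable-equal, 'ts', 'tv', or 'skip'."""
    if a not in ACGT or b not in ACGT:
        return "skip"
    if a == b:
        return "comp"
    if (a in PURINES) == (b in PURINES):
        return "ts"
    return "tv"


def pq_counts(a: str, b: str) -> tuple[int, int, int]:
    """(n_comparable, n_transitions, n_transversions) by direct scan."""
    n_comp = n_ts = n_tv = 0
    for x, y in zip(a, b):
        c = classify_column(x, y)
        if c == "skip":
            continue
        n_comp += 1
        if c == "ts":
            n_ts += 1
        elif c == "tv":
            n_tv += 1
    return n_comp, n_ts, n_tv


def k2p_closed_form(p: float, q: float) -> float:
    a = 1 - 2 * p - q
    b = 1 - 2 * q
    if a <= 0 or b <= 0:
        return math.nan
    return -0.5 * math.log(a) - 0.25 * math.log(b)


def oracle_k2p(a: str, b: str) -> float:
    n_comp, n_ts, n_tv = pq_counts(a, b)
    if n_comp == 0:
        return math.nan
    return k2p_closed_form(n_ts / n_comp, n_tv / n_comp)


def oracle_pi(seqs: list[str]) -> float:
    """Mean over unordered pairs of diffs/comparable (pairwise deletion)."""
    props = []
    n = len(seqs)
    for i in range(n):
        for j in range(i + 1, n):
            n_comp, n_ts, n_tv = pq_counts(seqs[i], seqs[j])
            if n_comp > 0:
                props.append((n_ts + n_tv) / n_comp)
    return sum(props) / len(props) if props else math.nan


def oracle_distance_matrix(seqs: list[str]) -> list[list[float]]:
    n = len(seqs)
    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = oracle_k2p(seqs[i], seqs[j])
            out[i][j] = out[j][i] = d
    return out


def oracle_near_neighbour(
    dist: list[list[float]], labels: list[str], tie_rule: str = "all"
) -> list[bool]:
    """Per-sample success flags by exhaustive re-scan of the matrix."""
    n = len(labels)
    successes = []
    for i in range(n):
        defined = [(dist[i][j], j) for j in range(n)
                   if j != i and not math.isnan(dist[i][j])]
        if not defined:
            successes.append(False)
            continue
        m = min(d for d, _ in defined)
        nearest = [j for d, j in defined if d == m]
        consp = [labels[j] == labels[i] for j in nearest]
        successes.append(all(consp) if tie_rule == "all" else any(consp))
    return successes


class WindowOracle:
    """Exhaustive window enumeration for Pm, independent of the package.

    Column classes per pair are computed by plain character loops; window
    aggregation sums slices of those class arrays directly (no prefix sums).
    """

    def __init__(self, seqs: list[str], labels: list[str]):
        self.n = len(seqs)
        self.L = len(seqs[0])
        self.labels = labels
        self.pairs = [(i, j) for i in range(self.n) for j in range(i + 1, self.n)]
        comp, ts, tv = [], [], []
        for i, j in self.pairs:
            c_row, t_row, v_row = [], [], []
            for x, y in zip(seqs[i], seqs[j]):
                cls = classify_column(x, y)
                c_row.append(cls in ("comp", "ts", "tv"))
                t_row.append(cls == "ts")
                v_row.append(cls == "tv")
            comp.append(c_row)
            ts.append(t_row)
            tv.append(v_row)
        self.comp = np.array(comp)
        self.ts = np.array(ts)
        self.tv = np.array(tv)

    def success_count(self, start: int, stop: int) -> int:
        n_comp = self.comp[:, start:stop].sum(axis=1)
        n_ts = self.ts[:, start:stop].sum(axis=1)
        n_tv = self.tv[:, start:stop].sum(axis=1)
        dist = [[0.0] * self.n for _ in range(self.n)]
        for k, (i, j) in enumerate(self.pairs):
            if n_comp[k] == 0:
                d = math.nan
            else:
                d = k2p_closed_form(n_ts[k] / n_comp[k], n_tv[k] / n_comp[k])
            dist[i][j] = dist[j][i] = d
        return sum(oracle_near_neighbour(dist, self.labels))

    def window_counts(self, length: int, step: int = 1) -> list[int]:
        return [
            self.success_count(s, s + length)
            for s in range(0, self.L - length + 1, step)
        ]

    def shortest(self, start: int = 50, increment: int = 10):
        """Exhaustive (length, window) search; returns
        (length, best_start, best_count, full_count)."""
        full = self.success_count(0, self.L)
        length = start
        while length <= self.L:
            counts = self.window_counts(length)
            best = max(counts)
            if best == full:
                return length, counts.index(best), best, full
            length += increment
        return self.L, 0, full, full


def oracle_substitution_scan(ref: str, other: str) -> list[tuple[int, str, str]]:
    """(ungapped ref pos, ref base, other base) by direct column scan."""
    out = []
    pos = 0
    for a, b in zip(ref, other):
        if a != "-":
            if a in ACGT and b in ACGT and a != b:
                out.append((pos, a, b))
            pos += 1
    return out


def oracle_indel_scan(ref: str, other: str) -> list[tuple[int, int, str]]:
    """(ref pos of preceding column, run length, carrier) for internal
    maximal gap runs, by direct scan."""
    events = []
    for carrier, seq in (("reference", ref), ("other", other)):
        i = 0
        while i < len(seq):
            if seq[i] != "-":
                i += 1
                continue
            start = i
            while i < len(seq) and seq[i] == "-":
                i += 1
            if start == 0 or i == len(seq):
                continue
            prev_ref_bases = sum(1 for c in ref[:start] if c != "-")
            events.append((max(prev_ref_bases - 1, 0), i - start, carrier))
    return sorted(events)
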