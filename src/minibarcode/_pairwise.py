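"""Vectorised per-column site classification for all sequence pairs.

Shared by the diversity and discrimination modules. A column is *comparable*
for a pair when both sequences carry an unambiguous base (pairwise deletion);
a comparable differing column is a transition when both bases are purines or
both pyrimidines, otherwise a transversion.
"""

from __future__ import annotations

import numpy as np


def pair_indices(n: int) -> list[tuple[int, int]]:
    """All unordered pairs (i, j), i < j, in row-major order."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def site_class_arrays(
    mat: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Per-pair boolean column classes for an (n, L) byte alignment matrix.

    Returns (comparable, transition, transversion) arrays of shape
    (n_pairs, L) plus the pair index list.
    """
    good = np.isin(mat, np.array([b"A", b"C", b"G", b"T"]))
    purine = np.isin(mat, np.array([b"A", b"G"]))
    pairs = pair_indices(mat.shape[0])
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    comp = good[ii] & good[jj]
    diff = comp & (mat[ii] != mat[jj])
    ts = diff & (purine[ii] == purine[jj])
    tv = diff & ~ts
    return comp, ts, tv, pairs
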