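import numpy as np
import pytest

from minibarcode import MarkerAlignment, SequenceRecord, SpeciesMap


def make_alignment(seqs, ids=None, name="test_marker"):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return MarkerAlignment(
        [SequenceRecord(i, s) for i, s in zip(ids, seqs)], marker_name=name
    )


def make_species_map(ids, labels):
    return SpeciesMap(dict(zip(ids, labels)))


def random_marker_alignment(rng, n_samples, n_cols, n_species):
    """A noisy random alignment with species structure for oracle tests:
    species consensus sequences plus per-sample noise, occasional gaps and
    ambiguity codes."""
    bases = np.array(list("ACGT"))
    ancestor = bases[rng.integers(0, 4, n_cols)]
    seqs, labels = [], []
    per = max(1, n_samples // n_species)
    sample = 0
    while sample < n_samples:
        sp = min(sample // per, n_species - 1)
        consensus = ancestor.copy()
        mask = rng.random(n_cols) < rng.uniform(0.01, 0.08)
        consensus[mask] = bases[rng.integers(0, 4, mask.sum())]
        seq = consensus.copy()
        mask = rng.random(n_cols) < 0.005
        seq[mask] = bases[rng.integers(0, 4, mask.sum())]
        gap_mask = rng.random(n_cols) < 0.01
        seq[gap_mask] = "-"
        amb_mask = rng.random(n_cols) < 0.005
        seq[amb_mask] = "N"
        seqs.append("".join(seq))
        labels.append(f"species_{sp}")
        sample += 1
    ids = [f"s{i}" for i in range(n_samples)]
    return make_alignment(seqs, ids), make_species_map(ids, labels), seqs, labels


@pytest.fixture
def tiny_alignment():
    return make_alignment(["ACGTACGTAC", "ACGTACGTAC", "ACTTACGTAC", "ACTTACGAAC"])
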