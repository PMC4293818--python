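import math

import numpy as np
import pytest

from minibarcode import (
    k2p_distance,
    k2p_from_proportions,
    k2p_matrix,
    near_neighbour,
    pm_length_curve,
    shortest_minibarcode,
    window_pm,
)
from minibarcode.core_io import SpeciesMap

from _oracles import (
    WindowOracle,
    k2p_closed_form,
    oracle_distance_matrix,
    oracle_k2p,
    oracle_near_neighbour,
)
from conftest import make_alignment, make_species_map, random_marker_alignment


def seq_with_counts(n_sites, n_ts, n_tv):
    """Pair of sequences realising exactly the requested P and Q counts."""
    a = "A" * n_sites
    b = "G" * n_ts + "C" * n_tv + "A" * (n_sites - n_ts - n_tv)
    return a, b


class TestK2PDistance:
    def test_identical_sequences(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_example(self):
        # 200 compared sites, 20 transitions, 10 transversions
        a, b = seq_with_counts(200, 20, 10)
        expected = -0.5 * math.log(1 - 2 * 0.1 - 0.05) - 0.25 * math.log(1 - 2 * 0.05)
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.1702, abs=5e-4)

    def test_undefined_outside_domain(self):
        # P = 0.5, Q = 0.1 -> 1 - 2P - Q <= 0
        a, b = seq_with_counts(100, 50, 10)
        assert math.isnan(k2p_distance(a, b))
        assert math.isnan(k2p_from_proportions(0.5, 0.1))

    def test_no_comparable_sites_undefined(self):
        assert math.isnan(k2p_distance("NN--", "AC--"))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            k2p_distance("ACGT", "ACG")

    def test_k2p_at_least_p_distance(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        for _ in range(20):
            a = "".join(bases[rng.integers(0, 4, 300)])
            b = list(a)
            for pos in rng.choice(300, 40, replace=False):
                b[pos] = bases[rng.integers(0, 4)]
            b = "".join(b)
            d = k2p_distance(a, b)
            p = sum(x != y for x, y in zip(a, b)) / 300
            if not math.isnan(d):
                assert d >= p - 1e-12


class TestK2PMatrix:
    def test_identical_sequences_zero_matrix(self):
        dm = k2p_matrix(make_alignment(["ACGT" * 10] * 3))
        assert (dm.values == 0).all()

    def test_matches_per_pair_closed_form(self):
        seqs = ["AAAAAAAAAA", "GGAAAAAAAA", "GGCCAAAAAA"]
        dm = k2p_matrix(make_alignment(seqs))
        want = oracle_distance_matrix(seqs)
        for i in range(3):
            for j in range(3):
                assert dm.values[i, j] == pytest.approx(want[i][j], abs=1e-12)

    def test_matches_ape_dist_dna_k80(self, tmp_path):
        """Cross-check against the independent K2P implementation in the R
        package ape (dist.dna, model K80, pairwise deletion)."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(17)
        aln, _, seqs, _ = random_marker_alignment(rng, 6, 200, 3)
        fasta = tmp_path / "aln.fasta"
        with open(fasta, "w") as fh:
            for sid, seq in zip(aln.sample_ids, seqs):
                fh.write(f">{sid}\n{seq}\n")
        script = (
            'suppressMessages(library(ape));'
            f'a <- read.dna("{fasta}", format="fasta");'
            'd <- dist.dna(a, model="K80", pairwise.deletion=TRUE);'
            'write.csv(as.matrix(d), stdout())'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        ).stdout
        import io

        import pandas as pd

        want = pd.read_csv(io.StringIO(out), index_col=0)
        got = k2p_matrix(aln).to_frame()
        for sid in aln.sample_ids:
            for sjd in aln.sample_ids:
                assert got.loc[sid, sjd] == pytest.approx(
                    want.loc[sid, sjd], abs=1e-8
                )

    def test_symmetric_zero_diagonal_on_random_input(self):
        rng = np.random.default_rng(4)
        aln, _, _, _ = random_marker_alignment(rng, 8, 150, 3)
        dm = k2p_matrix(aln)
        assert np.allclose(np.diag(dm.values), 0)
        sym = np.isclose(dm.values, dm.values.T) | (
            np.isnan(dm.values) & np.isnan(dm.values.T)
        )
        assert sym.all()


class TestNearNeighbour:
    def test_two_clean_species(self):
        aln = make_alignment(["AAAA", "AAAA", "CCCC", "CCCC"])
        sm = make_species_map(aln.sample_ids, ["X", "X", "Y", "Y"])
        res = near_neighbour(k2p_matrix(aln), sm)
        assert res.pm == 100.0
        assert all(res.per_species.values())

    def test_heterospecific_tie_fails_under_all_rule(self):
        # s0 is equidistant (one transition each) from conspecific s1 and
        # heterospecific s2
        aln = make_alignment(["AAAA", "AAGA", "AAAG", "CCCC"])
        sm = make_species_map(aln.sample_ids, ["X", "X", "Y", "Y"])
        res = near_neighbour(k2p_matrix(aln), sm)
        s0 = res.samples[0]
        assert set(s0.nearest) == {"s1", "s2"}
        assert not s0.success

    def test_heterospecific_tie_passes_under_any_rule(self):
        aln = make_alignment(["AAAA", "AAGA", "AAAG", "CCCC"])
        sm = make_species_map(aln.sample_ids, ["X", "X", "Y", "Y"])
        res = near_neighbour(k2p_matrix(aln), sm, tie_rule="any")
        assert res.samples[0].success

    def test_single_species_rejected(self):
        aln = make_alignment(["AAAA", "AACA"])
        sm = make_species_map(aln.sample_ids, ["X", "X"])
        with pytest.raises(ValueError, match="2 species"):
            near_neighbour(k2p_matrix(aln), sm)

    def test_sample_with_no_defined_distance_fails(self):
        aln = make_alignment(["NNNN", "AACA", "AAGA", "CCCC"])
        sm = make_species_map(aln.sample_ids, ["X", "X", "Y", "Y"])
        res = near_neighbour(k2p_matrix(aln), sm)
        assert not res.samples[0].success

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("tie_rule", ["all", "any"])
    def test_agrees_with_exhaustive_rescan(self, seed, tie_rule):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        aln, sm, seqs, labels = random_marker_alignment(
            rng, n, int(rng.integers(30, 200)), int(rng.integers(2, 5))
        )
        res = near_neighbour(k2p_matrix(aln), sm, tie_rule=tie_rule)
        want = oracle_near_neighbour(oracle_distance_matrix(seqs), labels, tie_rule)
        assert [s.success for s in res.samples] == want


class TestWindowScans:
    def test_full_length_window_reproduces_whole_marker_pm(self):
        rng = np.random.default_rng(2)
        aln, sm, _, _ = random_marker_alignment(rng, 9, 120, 3)
        scan = window_pm(aln, sm, window_length=aln.length)
        whole = near_neighbour(k2p_matrix(aln), sm)
        assert scan.max_pm == whole.pm
        assert scan.best_start == 0

    def test_diagnostic_block_windows_attain_maximum(self):
        # species-diagnostic variation confined to columns [10, 20)
        base = list("A" * 60)
        s1 = base[:]
        s2 = base[:]
        for c in range(10, 20):
            s1[c] = "G"
            s2[c] = "C"
        seqs = ["".join(base), "".join(base), "".join(s1), "".join(s1),
                "".join(s2), "".join(s2)]
        aln = make_alignment(seqs)
        sm = make_species_map(aln.sample_ids, ["X", "X", "Y", "Y", "Z", "Z"])
        scan = window_pm(aln, sm, window_length=25)
        oracle = WindowOracle(seqs, ["X", "X", "Y", "Y", "Z", "Z"])
        want = oracle.window_counts(25)
        assert scan.success_counts == want
        for start, count in zip(scan.starts, scan.success_counts):
            covers = start <= 10 and start + 25 >= 20
            if covers:
                assert count == max(want)

    def test_zero_variation_window_everyone_tied(self):
        aln = make_alignment(["AAAA", "AAAA", "AAAA", "AAAA"])
        sm = make_species_map(aln.sample_ids, ["X", "X", "Y", "Y"])
        scan = window_pm(aln, sm, window_length=4)
        # every sample's neighbour set is everyone -> heterospecific ties fail
        assert scan.max_pm == 0.0

    def test_curve_flat_for_single_diagnostic_column(self):
        base = "A" * 200
        variant = "A" * 100 + "G" + "A" * 99
        aln = make_alignment([base, base, variant, variant])
        sm = make_species_map(aln.sample_ids, ["X", "X", "Y", "Y"])
        curve = pm_length_curve(aln, sm, lengths=(50, 100, 150, 200))
        assert curve["max_pm"].nunique() == 1

    def test_longer_than_alignment_lengths_skipped(self):
        rng = np.random.default_rng(6)
        aln, sm, _, _ = random_marker_alignment(rng, 6, 120, 3)
        curve = pm_length_curve(aln, sm, lengths=(50, 100, 150, 200))
        assert list(curve["length"]) == [50, 100]


class TestShortestMinibarcode:
    def test_block_confined_variation_returns_start_length(self):
        rng = np.random.default_rng(8)
        from minibarcode import MarkerParams, simulate_marker_dataset

        aln, sm, _ = simulate_marker_dataset(
            MarkerParams(n_species=5, n_per_species=2, length=300,
                         between_divergence=0.3, within_divergence=0.0,
                         diagnostic_block=(100, 40)),
            seed=21,
        )
        res = shortest_minibarcode(aln, sm)
        assert res.shortest_length == 50
        assert res.best_window_start < 140 and res.best_window_start + 50 > 100
        assert res.pm_at_shortest == res.full_length_pm == 100.0

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed + 50)
        aln, sm, seqs, labels = random_marker_alignment(
            rng, int(rng.integers(4, 10)), int(rng.integers(80, 250)), 3
        )
        res = shortest_minibarcode(aln, sm)
        oracle = WindowOracle(seqs, labels)
        length, start, count, full = oracle.shortest()
        assert res.shortest_length == length
        assert res.best_window_start == start
        assert res.full_length_pm == pytest.approx(100 * full / len(seqs))

    def test_alignment_shorter_than_start_raises(self):
        aln = make_alignment(["ACGT" * 5, "AGGT" * 5])
        sm = make_species_map(aln.sample_ids, ["X", "Y"])
        with pytest.raises(ValueError, match="shorter"):
            shortest_minibarcode(aln, sm)
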