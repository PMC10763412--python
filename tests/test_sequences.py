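"""Tract detection, uAUG counting and motif primitives."""

import numpy as np
import pytest
from conftest import random_dna
from oracles import brute_a_runs, brute_oof_uaug

from polyutr import (
    UtrSequence,
    contains_motif,
    count_oof_uaug,
    find_polya_tracts,
    longest_polya,
    positional_motif,
)


class TestFindPolyATracts:
    @pytest.mark.parametrize(
        "seq,min_len,expected",
        [
            ("CGCGCG", 5, []),
            ("GGAAAAACC", 5, [(2, 7, 2)]),
            ("AAAAAGGAAAAAA", 5, [(0, 5, 8), (7, 13, 0)]),
            ("AANAAA", 5, []),  # N breaks a run
        ],
    )
    def test_examples(self, seq, min_len, expected):
        got = [(t.start, t.end, t.distance_to_aug) for t in find_polya_tracts(seq, min_len)]
        assert got == expected

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            seq = random_dna(rng, int(rng.integers(1, 61)), "ACGTN")
            for min_len in (1, 5):
                got = [(t.start, t.end) for t in find_polya_tracts(seq, min_len)]
                assert got == brute_a_runs(seq, min_len)

    def test_min_len_one_partitions_all_adenines(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            seq = random_dna(rng, int(rng.integers(1, 80)))
            tracts = find_polya_tracts(seq, min_len=1)
            assert sum(t.length for t in tracts) == seq.count("A")
            # maximality: flanks are never A
            for t in tracts:
                assert t.start == 0 or seq[t.start - 1] != "A"
                assert t.end == len(seq) or seq[t.end] != "A"


class TestLongestPolyA:
    def test_no_adenine_returns_none(self):
        assert longest_polya("CCCCG") is None

    def test_unique_longest(self):
        t = longest_polya("AAAAAGGAAAAAA")
        assert (t.length, t.distance_to_aug) == (6, 0)

    def test_tie_broken_to_three_prime(self):
        t = longest_polya("AAAAAGAAAAA")
        assert (t.start, t.distance_to_aug) == (6, 0)

    def test_tie_switchable_to_five_prime(self):
        t = longest_polya("AAAAAGAAAAA", tie="five_prime")
        assert t.start == 0

    def test_distance_reference_switch(self):
        t = longest_polya("GGAAAAACC", distance_ref="five_prime")
        assert t.distance_to_aug == 7  # measured from the tract's 5' end


class TestCountOofUaug:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("CCCCCC", 0),
            ("ATGAA", 1),     # out of frame: (5-0) % 3 == 2
            ("ATGTGA", 1),    # in frame with main AUG, but closed by a stop
            ("CCCATG", 0),    # in frame, no stop: not counted
        ],
    )
    def test_examples(self, seq, expected):
        assert count_oof_uaug(seq) == expected

    def test_double_qualifier_counts_once(self):
        # ATG out of frame AND reaching an in-frame stop
        seq = "ATGTAAC"  # (7-0)%3=1 out of frame; TAA at +3 closes a uORF
        assert count_oof_uaug(seq) == 1

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            seq = random_dna(rng, int(rng.integers(3, 61)))
            assert count_oof_uaug(seq) == brute_oof_uaug(seq)

    def test_strategy_switch_bounds_combined_count(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            seq = random_dna(rng, 50)
            combined = count_oof_uaug(seq)
            oof = count_oof_uaug(seq, strategy="oof_only")
            uorf = count_oof_uaug(seq, strategy="uorf_only")
            assert max(oof, uorf) <= combined <= oof + uorf


class TestMotifs:
    @pytest.mark.parametrize(
        "seq,motif,positions,expected",
        [
            ("GGGCA", "A", (-1,), 1),
            ("CCGGGGG", "CC", (-7, -6), 1),
            ("AG", "CC", (-7, -6), 0),  # too short to cover the window
            ("GGGTG", "A/G", (-3,), 1),
            ("GGGAC", "AC", (-2, -1), 1),
        ],
    )
    def test_positional(self, seq, motif, positions, expected):
        assert positional_motif(seq, motif, positions) == expected

    @pytest.mark.parametrize(
        "seq,motif,expected",
        [("TTGACATT", "GACA", 1), ("GAGA", "GG", 0), ("CACACC", "CACC", 1)],
    )
    def test_contains(self, seq, motif, expected):
        assert contains_motif(seq, motif) == expected

    def test_invariant_under_rna_encoding(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            seq = random_dna(rng, int(rng.integers(8, 40)))
            rna = seq.replace("T", "U").lower()
            assert contains_motif(seq, "CACC") == contains_motif(rna, "CACC")
            assert positional_motif(seq, "CC", (-7, -6)) == positional_motif(
                rna, "CC", (-7, -6)
            )

    def test_n_never_matches(self):
        assert positional_motif("GGGNN", "AA", (-2, -1)) == 0


class TestUtrSequence:
    def test_normalisation(self):
        u = UtrSequence("x", "acgu")
        assert u.seq == "ACGT"

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            UtrSequence("x", "ACGX")

    def test_base_at_aug_relative(self):
        u = UtrSequence("x", "GATTC", "ATGCC")
        assert u.base_at(-1) == "C"
        assert u.base_at(-5) == "G"
        assert u.base_at(-6) is None
        assert u.base_at(1) == "A"
        assert u.base_at(6) is None
        with pytest.raises(ValueError):
            u.base_at(0)
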