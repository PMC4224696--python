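"""PWM scoring, the conserved-position stringency filter, and motif
gain/loss calling."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_pssm, brute_scan, pwm
from oncocis import Mutation
from oncocis.motifs import (build_windows, conserved_positions, diff_motifs,
                            filter_motif_db, pssm_score, revcomp, scan,
                            scan_hits, stringent_match)

UNIFORM = pwm("UNIF", [(6, 6, 6, 6)] * 4)
ALL_A3 = pwm("A3", [(10, 0, 0, 0)] * 3)
MIXED4 = pwm("MIX4", [(8, 0, 2, 0), (0, 8, 2, 0), (2, 2, 4, 2), (4, 4, 2, 0)])


class TestPssmScore:
    def test_uniform_motif_scores_zero(self):
        assert pssm_score(UNIFORM, "ACGT") == 0.0

    def test_unanimous_motif_consensus_scores_two_bits_per_base(self):
        assert pssm_score(ALL_A3, "AAA") == pytest.approx(6.0)

    def test_mixed_matrix_matches_hand_computed_value(self):
        # frozen from an independent per-column log-ratio oracle
        assert pssm_score(MIXED4, "ACGG") == pytest.approx(3.712287620450551)

    def test_zero_frequency_base_gives_minus_inf(self):
        assert pssm_score(ALL_A3, "ACA") == float("-inf")

    def test_ambiguous_base_gives_minus_inf(self):
        assert pssm_score(UNIFORM, "ACNT") == float("-inf")

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.tuples(*[st.integers(0, 9)] * 4), min_size=1, max_size=6)
           .filter(lambda cols: all(sum(c) > 0 for c in cols)),
           st.randoms(use_true_random=False))
    def test_agrees_with_independent_scorer(self, cols, rnd):
        motif = pwm("X", cols)
        seq = "".join(rnd.choice("ACGT") for _ in cols)
        expected = brute_pssm(cols, seq)
        got = pssm_score(motif, seq)
        if math.isinf(expected):
            assert math.isinf(got)
        else:
            assert got == pytest.approx(expected)

    def test_consensus_is_argmax_over_all_sequences(self):
        # exhaustive over 4^W for small widths
        for motif in (MIXED4, pwm("Y", [(5, 3, 1, 1), (0, 9, 1, 0), (2, 2, 3, 3)])):
            best = max(pssm_score(motif, "".join(s))
                       for s in itertools.product("ACGT", repeat=motif.width))
            assert pssm_score(motif, motif.consensus) == pytest.approx(best)


class TestConservedPositions:
    def test_above_threshold_included(self):
        motif = pwm("X", [(9, 1, 0, 0), (3, 3, 2, 2)])
        assert conserved_positions(motif) == {(0, "A")}

    def test_exact_threshold_excluded(self):
        motif = pwm("X", [(8, 2, 0, 0)])  # q(A) = 0.8 exactly
        assert conserved_positions(motif, 0.8) == set()

    def test_uniform_motif_has_none(self):
        assert conserved_positions(UNIFORM) == set()


class TestStringentMatch:
    def test_requires_all_conserved_positions(self):
        motif = pwm("X", [(9, 1, 0, 0), (3, 3, 2, 2), (0, 0, 10, 0)])
        assert stringent_match(motif, "ATG")
        assert not stringent_match(motif, "CTG")  # conserved pos 0 mismatched

    def test_no_conserved_positions_always_passes(self):
        assert stringent_match(UNIFORM, "GGGG")


class TestFilterMotifDb:
    def test_taxon_and_strict_site_count(self):
        motifs = [pwm("A", [(25, 0, 0, 0)], taxon="mammals"),
                  pwm("B", [(20, 0, 0, 0)], taxon="mammals"),   # exactly 20
                  pwm("C", [(25, 0, 0, 0)], taxon="insects"),
                  pwm("D", [(30, 0, 0, 0)], taxon="vertebrates")]
        kept = filter_motif_db(motifs, {"mammals", "vertebrates"}, 20)
        assert [m.name for m in kept] == ["A", "D"]

    def test_empty_input(self):
        assert filter_motif_db([], {"mammals"}, 20) == []


class TestBuildWindows:
    GENOME = {"chr1": "ACGT" * 30}

    def test_substitution_windows(self):
        m = Mutation("chr1", 60, "T", "A", "S")  # base 60 is T
        wt, mut = build_windows(m, self.GENOME, pad=20)
        assert len(wt) == len(mut) == 41
        assert wt[20] == "T" and mut[20] == "A"
        assert wt[:20] == mut[:20] and wt[21:] == mut[21:]

    def test_deletion_windows_differ_in_length(self):
        m = Mutation("chr1", 60, "TA", "", "S")
        wt, mut = build_windows(m, self.GENOME, pad=20)
        assert len(wt) == 42 and len(mut) == 40
        assert wt[:20] == mut[:20] and wt[22:] == mut[20:]

    def test_reference_mismatch_is_an_error(self):
        m = Mutation("chr1", 60, "G", "A", "S")
        with pytest.raises(ValueError, match="chr1:60"):
            build_windows(m, self.GENOME)


class TestScan:
    FIX_MOTIFS = [
        pwm("ETS6", [(0, 25, 0, 0), (0, 0, 25, 0), (0, 0, 25, 0),
                     (25, 0, 0, 0), (25, 0, 0, 0), (0, 0, 25, 0)]),  # CGGAAG
        MIXED4, UNIFORM,
        pwm("PAL4", [(0, 0, 25, 0), (25, 0, 0, 0), (0, 0, 0, 25),
                     (0, 25, 0, 0)]),  # GATC palindrome
    ]

    def test_planted_consensus_found(self):
        seq = "TTTTTTTTTT" + "CGGAAG" + "TTTTTTTTTT"
        assert "ETS6" in scan(seq, self.FIX_MOTIFS)

    def test_minus_strand_detection(self):
        seq = "TTTTTTTTTT" + revcomp("CGGAAG") + "TTTTTTTTTT"
        hits = scan_hits(seq, [self.FIX_MOTIFS[0]])
        assert {h.strand for h in hits} == {"-"}

    def test_all_n_sequence_yields_nothing(self):
        assert scan("N" * 30, self.FIX_MOTIFS) == set()

    def test_palindrome_reported_once_with_equal_strand_scores(self):
        seq = "TTTTT" + "GATC" + "TTTTT"
        hits = scan_hits(seq, [self.FIX_MOTIFS[3]])
        by_strand = {h.strand: h.score for h in hits if h.offset == 5}
        assert by_strand["+"] == pytest.approx(by_strand["-"])
        assert scan(seq, [self.FIX_MOTIFS[3]]) == {"PAL4"}

    @settings(max_examples=25, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=8, max_size=60),
           st.floats(min_value=0.0, max_value=8.0),
           st.sampled_from([0.5, 0.8, 0.95]))
    def test_equals_brute_force_enumeration(self, seq, cutoff, threshold):
        assert scan(seq, self.FIX_MOTIFS, cutoff, threshold) == \
            brute_scan(seq, self.FIX_MOTIFS, cutoff, threshold)

    @settings(max_examples=25, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=10, max_size=50))
    def test_tightening_parameters_never_adds_hits(self, seq):
        # raising the score cutoff shrinks the hit set; lowering the
        # conserved-position threshold classifies more positions as
        # conserved, adding match constraints, so it shrinks it too
        loose = scan(seq, self.FIX_MOTIFS, cutoff=2.0, threshold=0.95)
        tight = scan(seq, self.FIX_MOTIFS, cutoff=6.0, threshold=0.95)
        assert tight <= loose
        constrained = scan(seq, self.FIX_MOTIFS, cutoff=2.0, threshold=0.5)
        assert constrained <= loose


class TestDiffMotifs:
    def test_set_differences(self):
        created, removed = diff_motifs({"A", "B"}, {"B", "C"})
        assert created == {"C"} and removed == {"A"}
        assert diff_motifs({"A"}, {"A"}) == (set(), set())

    def test_created_and_removed_always_disjoint(self):
        for wt, mut in [({"A"}, {"B"}), (set(), {"X", "Y"}), ({"Z"}, set())]:
            c, r = diff_motifs(wt, mut)
            assert not c & r

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 1000))
    def test_substitution_outside_hit_changes_nothing(self, seed):
        # a TF whose hits never cover the mutated base ends up in neither set
        rng = np.random.default_rng(seed)
        left = "".join(rng.choice(list("ACT"), size=15))
        right = "".join(rng.choice(list("ACT"), size=15))
        wt = left + "CGGAAG" + right  # mutation will hit the right flank only
        mut = wt[:30] + "A" + wt[31:]
        if wt == mut:
            return
        motif = [self_m for self_m in TestScan.FIX_MOTIFS if self_m.name == "ETS6"]
        created, removed = diff_motifs(scan(wt, motif), scan(mut, motif))
        assert created == set() and removed == set()
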