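import random

import pytest

import xenqc as xq
from xenqc import CompletenessClass as C
from xenqc.errors import InputError
from xenqc.orf_scan import CompletenessParams

from .conftest import brute_force_longest_orf


@pytest.mark.parametrize(
    "seq,offset,expected",
    [
        ("ATGAAA", 0, "MK"),
        ("ATGAAN", 0, "MX"),
        ("ATGTAA", 0, "M*"),
        ("AATGAAA", 1, "MK"),
        ("ATGA", 0, "M"),  # trailing partial codon dropped
    ],
)
def test_translate(seq, offset, expected):
    assert xq.translate(seq, offset) == expected


class TestFindLongestOrf:
    def test_simple_orf_with_stop(self):
        orf = xq.find_longest_orf("GGATGAAATAGCC", min_len_nt=6)
        assert (orf.start, orf.end) == (2, 11)
        assert orf.has_start and orf.has_stop
        assert orf.protein == "MK"

    def test_length_tie_broken_by_most_5prime_start(self):
        orf = xq.find_longest_orf("ATGAAATAGATGCCCTAG", min_len_nt=6)
        assert orf.start == 0

    def test_no_atg_anywhere(self):
        assert xq.find_longest_orf("GGGCCCGGGCCC") is None

    def test_open_ended_orf_runs_to_last_complete_codon(self):
        orf = xq.find_longest_orf("GGATGAAAAAA", min_len_nt=6)
        assert (orf.start, orf.end) == (2, 11)
        assert not orf.has_stop

    def test_min_length_filter(self):
        assert xq.find_longest_orf("GGATGAAATAGCC", min_len_nt=12) is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            xq.find_longest_orf("")

    def test_reverse_strand_scan(self):
        fwd = "GGATGAAATAGCC"
        rc = xq.orf_scan.reverse_complement(fwd)
        orf = xq.find_longest_orf(rc, min_len_nt=6, scan_reverse=True)
        assert orf.strand == "-"
        # mapped back onto the forward input: complement of positions 2..11
        assert (orf.start, orf.end) == (len(fwd) - 11, len(fwd) - 2)
        assert orf.protein == "MK"

    def test_oracle_equivalence_on_random_sequences(self):
        """The finder agrees with exhaustive enumeration over all
        (ATG position, frame) pairs on >=1000 random sequences <=90 nt."""
        rng = random.Random(42)
        n_checked = 0
        for i in range(1100):
            length = rng.randint(1, 90)
            alphabet = "ACGT" if i % 4 else "ACGTN"
            seq = "".join(rng.choice(alphabet) for _ in range(length))
            expected = brute_force_longest_orf(seq, min_len_nt=6)
            got = xq.find_longest_orf(seq, min_len_nt=6)
            if expected is None:
                assert got is None, seq
            else:
                assert got is not None, seq
                assert (got.start, got.end, got.has_stop) == expected, seq
            n_checked += 1
        assert n_checked >= 1000


class TestClassifyCompleteness:
    def orf(self, seq, min_len=6):
        return xq.find_longest_orf(seq, min_len_nt=min_len)

    def test_both_utrs(self):
        seq = "GGATGAAATAGCC"
        assert xq.classify_completeness(seq, self.orf(seq)) == C.COMPLETE_WITH_UTRS

    def test_orf_runs_to_5prime_end(self):
        seq = "ATGAAATAGCC"
        assert xq.classify_completeness(seq, self.orf(seq)) == C.COMPLETE_NO_5UTR

    def test_orf_runs_to_3prime_end(self):
        seq = "GGATGAAATAG"
        assert xq.classify_completeness(seq, self.orf(seq)) == C.COMPLETE_NO_3UTR

    def test_no_utrs(self):
        seq = "ATGAAATAG"
        assert xq.classify_completeness(seq, self.orf(seq)) == C.COMPLETE_NO_UTRS

    def test_missing_stop_is_trunc3(self):
        seq = "GGATGAAAAAA"
        assert xq.classify_completeness(seq, self.orf(seq)) == C.TRUNC_3

    def test_repeat_precedence_overrides_everything(self):
        seq = "GGATGAAATAGCC"
        cls = xq.classify_completeness(seq, self.orf(seq), repeat_fraction=0.81)
        assert cls == C.HIGH_COPY_REPEAT

    def test_repeat_boundary_is_strict(self):
        seq = "GGATGAAATAGCC"
        assert xq.classify_completeness(seq, self.orf(seq), repeat_fraction=0.80) \
            == C.COMPLETE_WITH_UTRS

    def test_repeat_fraction_out_of_range(self):
        with pytest.raises(InputError):
            xq.classify_completeness("ACGT", None, repeat_fraction=1.2)

    def test_evidence_upstream_of_start_is_trunc5(self):
        # open upstream frame but short (<30 nt): heuristic silent, evidence speaks
        seq = "C" * 10 + "ATG" + "AAA" * 20 + "TAG" + "CC"
        orf = self.orf(seq)
        assert orf.start == 10
        assert xq.classify_completeness(seq, orf, protein_evidence=[(2, 9)]) == C.TRUNC_5
        assert xq.classify_completeness(seq, orf, protein_evidence=[(12, 30)]) \
            == C.COMPLETE_WITH_UTRS

    def test_heuristic_trunc5_needs_long_open_upstream(self):
        # 36 nt of stop-free in-frame sequence upstream of the ATG
        seq = "CAC" * 12 + "ATG" + "AAA" * 20 + "TAG"
        orf = self.orf(seq)
        assert xq.classify_completeness(seq, orf) == C.TRUNC_5
        # an in-frame stop upstream blocks the heuristic
        seq2 = "CAC" * 11 + "TAA" + "ATG" + "AAA" * 20 + "TAG" + "GG"
        orf2 = self.orf(seq2)
        assert xq.classify_completeness(seq2, orf2) == C.COMPLETE_WITH_UTRS

    def test_trunc_both(self):
        seq = "CAC" * 12 + "ATG" + "AAA" * 20
        orf = self.orf(seq)
        assert not orf.has_stop
        assert xq.classify_completeness(seq, orf) == C.TRUNC_BOTH

    def test_no_orf(self):
        assert xq.classify_completeness("GGGCCC", None) == C.NO_ORF

    def test_total_function_one_class(self, transcript_recovery):
        _, _, calls = transcript_recovery
        assert all(isinstance(c, C) for c in calls.values())

    def test_repeat_monotonicity_across_boundary(self):
        """Raising repeat_fraction through 0.80 only ever flips the class
        to HIGH_COPY_REPEAT, never to anything else."""
        seq = "GGATGAAATAGCC"
        orf = self.orf(seq)
        below = xq.classify_completeness(seq, orf, repeat_fraction=0.80)
        for frac in (0.801, 0.9, 1.0):
            above = xq.classify_completeness(seq, orf, repeat_fraction=frac)
            assert above == C.HIGH_COPY_REPEAT
        assert below != C.HIGH_COPY_REPEAT


class TestTally:
    def test_counts_and_total(self):
        tally = xq.tally_classes(
            [("t1", C.TRUNC_3), ("t2", C.TRUNC_3), ("t3", C.COMPLETE_NO_UTRS)],
            "demo",
        )
        assert tally.counts == {C.TRUNC_3: 2, C.COMPLETE_NO_UTRS: 1}
        assert tally.total == 3

    def test_duplicate_id_rejected(self):
        with pytest.raises(InputError, match="t1"):
            xq.tally_classes([("t1", C.TRUNC_3), ("t1", C.TRUNC_3)], "demo")

    def test_empty_input(self):
        tally = xq.tally_classes([], "demo")
        assert tally.total == 0 and tally.counts == {}

    def test_conservation_on_recovered_set(self, transcript_recovery):
        _, truths, calls = transcript_recovery
        tally = xq.tally_classes(sorted(calls.items()), "synthetic")
        assert tally.total == len(truths)
        assert sum(tally.counts.values()) == tally.total
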