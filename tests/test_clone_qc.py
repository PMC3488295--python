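import random

import pytest

import xenqc as xq
from xenqc import CloneQcCode as Q
from xenqc.clone_qc import ContigReference, detect_frameshifts
from xenqc.errors import InputError
from xenqc.seqio import SeqRecord


def rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="module")
def contig():
    """One coding contig: 100 nt UTR5, 1200 nt ORF (incl. stop), 150 nt UTR3."""
    contigs, _, _, _ = xq.make_clone_set(
        xq.CloneSetSpec(defects=["perfect"], orf_codons=400, seed=5)
    )
    return contigs[0]


class TestAlignToContig:
    def test_identical_clone(self, contig):
        aln = xq.align_to_contig(SeqRecord("c", contig.seq), contig)
        assert aln.identity == 1.0
        assert aln.q_cov == 1.0 and aln.t_cov == 1.0

    def test_single_deletion_position(self, contig):
        seq = contig.seq[:250] + contig.seq[251:]
        aln = xq.align_to_contig(SeqRecord("c", seq), contig)
        net = xq.net_indels(aln)
        assert len(net) == 1
        assert net[0].kind == "deletion_from_query"
        # equivalent placements shift the gap when flanking bases repeat
        assert abs(net[0].t_pos - 250) <= 2 and net[0].length == 1

    def test_reverse_complement_clone(self, contig):
        rc = xq.orf_scan.reverse_complement(contig.seq)
        aln = xq.align_to_contig(SeqRecord("c", rc), contig)
        assert aln.strand == "-" and aln.identity == 1.0


class TestDetectFrameshifts:
    def make_aln(self, contig, seq):
        return xq.align_to_contig(SeqRecord("c", seq), contig)

    def test_one_nt_deletion_in_orf(self, contig):
        mid = (contig.orf_start + contig.orf_end) // 2
        aln = self.make_aln(contig, contig.seq[:mid] + contig.seq[mid + 1 :])
        assert len(detect_frameshifts(aln, (contig.orf_start, contig.orf_end))) == 1

    def test_in_frame_deletion_is_not_a_frameshift(self, contig):
        mid = (contig.orf_start + contig.orf_end) // 2
        aln = self.make_aln(contig, contig.seq[:mid] + contig.seq[mid + 3 :])
        assert detect_frameshifts(aln, (contig.orf_start, contig.orf_end)) == []

    def test_indel_outside_orf_ignored(self, contig):
        pos = contig.orf_end + 50  # in the 3' UTR
        aln = self.make_aln(contig, contig.seq[:pos] + "A" + contig.seq[pos:])
        assert detect_frameshifts(aln, (contig.orf_start, contig.orf_end)) == []

    def test_null_orf_gives_nothing(self, contig):
        aln = self.make_aln(contig, contig.seq[:300] + contig.seq[301:])
        assert detect_frameshifts(aln, None) == []


class TestClassifyClone:
    def test_perfect_clone_is_fl(self, contig):
        call = xq.classify_clone(SeqRecord("c", contig.seq), [contig])
        assert call.code == Q.FL

    def test_mostly_n_clone_is_unknown(self, contig):
        n = len(contig.seq)
        seq = "N" * (n // 2 + 10) + contig.seq[n // 2 + 10 :]
        call = xq.classify_clone(SeqRecord("c", seq), [contig])
        assert call.code == Q.UNKNOWN

    def test_five_prime_truncation(self, contig):
        call = xq.classify_clone(
            SeqRecord("c", contig.seq[contig.orf_start + 50 :]), [contig]
        )
        assert call.code == Q.FLt5

    def test_truncated_both_ends_maps_to_flt5(self, contig):
        seq = contig.seq[contig.orf_start + 50 : contig.orf_end - 50]
        call = xq.classify_clone(SeqRecord("c", seq), [contig])
        assert call.code == Q.FLt5

    def test_empty_candidates_rejected(self, contig):
        with pytest.raises(InputError):
            xq.classify_clone(SeqRecord("c", contig.seq), [])

    def test_candidate_order_never_changes_the_code(self, clone_set):
        contigs, _, clones, _ = clone_set
        rng = random.Random(99)
        for rec in clones[:6]:
            base = xq.classify_clone(rec, contigs).code
            shuffled = list(contigs)
            rng.shuffle(shuffled)
            assert xq.classify_clone(rec, shuffled).code == base

    def test_truth_recovery_on_unambiguous_set(self, clone_recovery):
        """Every unambiguous synthetic defect label is recovered exactly."""
        truths, calls = clone_recovery
        scored = [t for t in truths if t.true_code is not None]
        assert len(scored) >= 50
        misses = [
            (t.clone_id, t.defect, t.true_code, calls[t.clone_id].code)
            for t in scored
            if calls[t.clone_id].code != t.true_code
        ]
        assert misses == []

    def test_every_code_exercised(self, clone_recovery):
        truths, calls = clone_recovery
        seen = {calls[t.clone_id].code for t in truths}
        assert seen == {
            Q.FL, Q.FLt5, Q.FLt3, Q.FS, Q.CHI, Q.IMM, Q.FLsh, Q.FLq, Q.FLx
        }

    def test_rationale_names_the_evidence(self, contig):
        call = xq.classify_clone(
            SeqRecord("c", contig.seq[contig.orf_start + 50 :]), [contig]
        )
        assert "5'" in call.rationale


class TestQcSummary:
    def test_counts_and_conservation(self):
        tally = xq.qc_summary(
            [("a", Q.FL), ("b", Q.FL), ("c", Q.FS)], "demo"
        )
        assert tally.counts == {Q.FL: 2, Q.FS: 1} and tally.total == 3

    def test_duplicate_clone_rejected(self):
        with pytest.raises(InputError):
            xq.qc_summary([("a", Q.FL), ("a", Q.FS)], "demo")

    def test_empty(self):
        assert xq.qc_summary([], "demo").total == 0


def test_contig_reference_validation():
    with pytest.raises(ValueError):
        ContigReference("x", "ACGTACGT", 0, 4)  # length not divisible by 3
    with pytest.raises(ValueError):
        ContigReference("x", "ACGTACGT", 2, None)
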