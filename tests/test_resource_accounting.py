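import pytest

import xenqc as xq
from xenqc import CloneQcCode as Q
from xenqc.errors import InputError
from xenqc.orf_scan import CategoryTally
from xenqc.resource_accounting import CloneRecord, GeneMap


def make_clones(set_name, species, pairs):
    """pairs: list of (clone_id, accession-or-None)."""
    return [
        CloneRecord(cid, set_name, species, accession=acc)
        for cid, acc in pairs
    ]


GM = GeneMap({"a1": "g1", "a2": "g1", "a3": "g2", "b1": "g2", "b2": "g3"})


class TestSummarizeSet:
    def test_distinct_genes_and_unmapped(self):
        clones = make_clones(
            "setA", "Xt",
            [("c1", "a1"), ("c2", "a2"), ("c3", "a3"), ("c4", "zz"), ("c5", "zz2")],
        )
        s = xq.summarize_set(clones, GM, plates=1, fl_rate=1.0)
        assert s.distinct_clones == 5
        assert s.distinct_genes == 2
        assert s.unmapped_accessions == 2
        assert s.est_fl_genes == 2

    def test_published_estimator_example(self):
        """4973 distinct genes at a 90% full-length rate rounds to 4476."""
        gm = GeneMap({f"a{i}": f"g{i}" for i in range(4973)})
        clones = make_clones(
            "IMAGE/XGC", "Xt", [(f"c{i}", f"a{i}") for i in range(4973)]
        )
        s = xq.summarize_set(clones, gm, plates=54, fl_rate=0.90)
        assert s.est_fl_genes == 4476
        assert s.wells == 5184

    def test_empty_set(self):
        s = xq.summarize_set([], GM, plates=1, fl_rate=0.5, set_name="empty")
        assert s.distinct_clones == s.distinct_genes == s.est_fl_genes == 0

    def test_order_invariance(self):
        clones = make_clones(
            "setA", "Xt", [("c1", "a1"), ("c2", "a3"), ("c3", None)]
        )
        a = xq.summarize_set(clones, GM, plates=1, fl_rate=0.5)
        b = xq.summarize_set(list(reversed(clones)), GM, plates=1, fl_rate=0.5,
                             set_name=a.set_name)
        assert a == b

    def test_bad_plates_rejected(self):
        with pytest.raises(InputError):
            xq.summarize_set([], GM, plates=0, fl_rate=0.5)

    def test_est_fl_monotone_in_rate(self):
        clones = make_clones(
            "setA", "Xt", [("c1", "a1"), ("c2", "a3"), ("c3", "b2")]
        )
        prev = -1
        for rate in (0.0, 0.3, 0.5, 0.9, 1.0):
            est = xq.summarize_set(clones, GM, plates=1, fl_rate=rate).est_fl_genes
            assert est >= prev
            prev = est


class TestFlRateFromQc:
    def test_sequenced_denominator_excludes_unknown(self):
        tally = xq.fixture_tally("wellcome_sanger_qc")
        rate = xq.fl_rate_from_qc(tally)
        assert rate == pytest.approx(4585 / (9216 - 2772))
        assert rate > 0.70

    def test_image_sample_rate(self):
        rate = xq.fl_rate_from_qc(xq.fixture_tally("image_xgc_qc"))
        assert rate == pytest.approx(1795 / (1920 - 4))
        assert rate > 0.90

    def test_all_fl(self):
        tally = CategoryTally("t", {Q.FL: 1}, 1)
        assert xq.fl_rate_from_qc(tally) == 1.0

    def test_zero_denominator_rejected(self):
        tally = CategoryTally("t", {Q.UNKNOWN: 3}, 3)
        with pytest.raises(InputError):
            xq.fl_rate_from_qc(tally)


class TestCombineSets:
    def _two_sets(self, pairs_a, pairs_b, gm):
        ta = make_clones("A", "Xt", pairs_a)
        tb = make_clones("B", "Xt", pairs_b)
        sa = xq.summarize_set(ta, gm, plates=1, fl_rate=1.0, set_name="A")
        sb = xq.summarize_set(tb, gm, plates=1, fl_rate=1.0, set_name="B")
        return xq.combine_sets([sa, sb], [ta, tb], gm), sa, sb

    def test_shared_gene_deduplicated(self):
        combined, sa, sb = self._two_sets(
            [("c1", "a1"), ("c2", "a3")],  # {g1, g2}
            [("d1", "b1"), ("d2", "b2")],  # {g2, g3}
            GM,
        )
        assert combined.distinct_genes == 3
        assert combined.distinct_genes < sa.distinct_genes + sb.distinct_genes

    def test_disjoint_sets_sum(self):
        combined, sa, sb = self._two_sets(
            [("c1", "a1")], [("d1", "b2")], GM
        )
        assert combined.distinct_genes == sa.distinct_genes + sb.distinct_genes
        assert combined.plates == 2 and combined.wells == 192

    def test_single_set_identity(self):
        clones = make_clones("A", "Xt", [("c1", "a1")])
        s = xq.summarize_set(clones, GM, plates=1, fl_rate=1.0, set_name="A")
        assert xq.combine_sets([s], [clones], GM) == s

    def test_species_mismatch_rejected(self):
        ta = make_clones("A", "Xt", [("c1", "a1")])
        tb = make_clones("B", "Xl", [("d1", "b1")])
        sa = xq.summarize_set(ta, GM, plates=1, fl_rate=1.0, set_name="A")
        sb = xq.summarize_set(tb, GM, plates=1, fl_rate=1.0, set_name="B")
        with pytest.raises(InputError):
            xq.combine_sets([sa, sb], [ta, tb], GM)


class TestCoveragePercent:
    @pytest.mark.parametrize(
        "n,total,expected",
        [(10_549, 22_472, 46.9), (10_549, 20_000, 52.7), (0, 100, 0.0)],
    )
    def test_published_coverage_figures(self, n, total, expected):
        assert xq.coverage_percent(n, total) == expected

    def test_zero_denominator(self):
        with pytest.raises(InputError):
            xq.coverage_percent(1, 0)
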