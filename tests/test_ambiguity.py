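"""Junction sequence construction, hit scoring and ambiguity classification."""

import pytest
from Bio.Seq import Seq

from nclscreen import ambiguity as amb
from nclscreen import harmonize as hz
from nclscreen import io_formats as io


def make_hit(
    matches=200,
    misMatches=0,
    repMatches=0,
    qNumInsert=0,
    tNumInsert=0,
    qName="q",
    qSize=200,
    qStart=0,
    qEnd=200,
    tName="chr1",
    tStart=0,
    tEnd=200,
    strand="+",
):
    return io.PSLHit(
        matches=matches, misMatches=misMatches, repMatches=repMatches, nCount=0,
        qNumInsert=qNumInsert, qBaseInsert=0, tNumInsert=tNumInsert, tBaseInsert=0,
        strand=strand, qName=qName, qSize=qSize, qStart=qStart, qEnd=qEnd,
        tName=tName, tSize=10**6, tStart=tStart, tEnd=tEnd,
        blockCount=1, blockSizes=(qEnd - qStart,), qStarts=(qStart,), tStarts=(tStart,),
    )


def _event(key, donor_genes={"G"}, acceptor_genes={"G"}):
    return hz.NCLEvent(key, {"t": 5}, frozenset(donor_genes), frozenset(acceptor_genes))


def _jseq(key=None, d=100, a=100):
    key = key or io.EventKey("chr1", 5000, "+", "chr1", 4801, "+")
    return amb.JunctionSequence(key, "A" * (d + a), d, a)


class TestScoreHit:
    def test_web_blat_convention(self):
        score, identity = amb.score_hit(
            make_hit(matches=190, misMatches=5, qNumInsert=1, tNumInsert=1)
        )
        assert score == 183 and identity == pytest.approx(0.95)

    def test_perfect_hit(self):
        assert amb.score_hit(make_hit()) == (200, 1.0)

    def test_identity_at_exactly_080_is_not_above_threshold(self):
        _, identity = amb.score_hit(make_hit(matches=160, misMatches=40))
        assert identity == pytest.approx(0.80)
        assert amb.find_alt_colinear([make_hit(matches=160, misMatches=40)], _jseq()) is None

    def test_zero_query_size_is_an_error(self):
        with pytest.raises(ValueError):
            amb.score_hit(make_hit(qSize=0))


class TestAltColinear:
    def test_midpoint_crossing_high_identity_hit_qualifies(self):
        hit = make_hit(matches=165, misMatches=35)  # identity 0.825
        assert amb.find_alt_colinear([hit], _jseq()) is hit

    def test_hit_not_crossing_midpoint_is_ignored(self):
        hit = make_hit(matches=95, qStart=0, qEnd=95)
        assert amb.find_alt_colinear([hit], _jseq()) is None

    def test_identity_below_threshold_is_ignored(self):
        hit = make_hit(matches=158, misMatches=42)  # identity 0.79
        assert amb.find_alt_colinear([hit], _jseq()) is None

    def test_side_margin_guards_clipped_hits(self):
        # crosses the midpoint but with only 5 query bases on the right side
        hit = make_hit(matches=105, qStart=0, qEnd=105)
        assert amb.find_alt_colinear([hit], _jseq(), identity_threshold=0.5) is None
        assert (
            amb.find_alt_colinear([hit], _jseq(), identity_threshold=0.5, side_margin=5)
            is hit
        )

    def test_raising_threshold_never_adds_calls(self):
        hits = [make_hit(matches=165, misMatches=35)]
        low = amb.find_alt_colinear(hits, _jseq(), identity_threshold=0.80)
        high = amb.find_alt_colinear(hits, _jseq(), identity_threshold=0.90)
        assert low is not None and high is None


class TestMultiHit:
    def test_runner_up_within_gap_flags(self):
        hits = [
            make_hit(matches=183, tStart=1000, tEnd=1200),
            make_hit(matches=181, tStart=50_000, tEnd=50_200),
        ]
        flag, best, runner = amb.find_multi_hit(hits)
        assert flag and best == 183 and runner == 181

    def test_gap_of_four_does_not_flag(self):
        hits = [
            make_hit(matches=183, tStart=1000, tEnd=1200),
            make_hit(matches=179, tStart=50_000, tEnd=50_200),
        ]
        assert amb.find_multi_hit(hits)[0] is False

    def test_duplicate_lines_collapse_to_one_locus(self):
        hit = make_hit(matches=183, tStart=1000, tEnd=1200)
        assert amb.find_multi_hit([hit, hit])[0] is False

    def test_self_locus_pair_counts_as_one_locus(self):
        key = io.EventKey("chr1", 5000, "+", "chr1", 40_000, "+")
        self_regions = [("chr1", 4800, 5200), ("chr1", 39_800, 40_200)]
        hits = [
            make_hit(matches=100, qStart=0, qEnd=100, tStart=4900, tEnd=5000),
            make_hit(matches=100, qStart=100, qEnd=200, tStart=39_999, tEnd=40_099),
        ]
        assert amb.find_multi_hit(hits, self_regions=self_regions)[0] is False

    def test_low_coverage_hits_are_ignored(self):
        hits = [
            make_hit(matches=183, tStart=1000, tEnd=1200),
            make_hit(matches=90, qStart=0, qEnd=90, tStart=50_000, tEnd=50_090),
        ]
        assert amb.find_multi_hit(hits)[0] is False

    def test_widening_gap_never_removes_calls(self):
        hits = [
            make_hit(matches=183, tStart=1000, tEnd=1200),
            make_hit(matches=179, tStart=50_000, tEnd=50_200),
        ]
        assert amb.find_multi_hit(hits, score_gap=3)[0] is False
        assert amb.find_multi_hit(hits, score_gap=10)[0] is True


class TestClassify:
    KEY = io.EventKey("chr1", 5000, "+", "chr1", 40_000, "+")

    def test_alt_colinear_takes_precedence_over_multi_hit(self):
        alt = make_hit(matches=170, misMatches=30, tName="TX9")
        dup1 = make_hit(matches=100, qStart=0, qEnd=100, tStart=70_000, tEnd=70_100)
        dup2 = make_hit(matches=99, misMatches=1, qStart=0, qEnd=100,
                        tStart=90_000, tEnd=90_100)
        call = amb.classify_ambiguity(
            _event(self.KEY), [alt, dup1, dup2], _jseq(self.KEY), {"chr1"}
        )
        assert call.status == "alt_colinear"
        assert call.alt_flag and call.multi_flag

    def test_no_qualifying_hits_is_ok(self):
        self_d = make_hit(matches=100, qStart=0, qEnd=100, tStart=4900, tEnd=5000)
        self_a = make_hit(matches=100, qStart=100, qEnd=200, tStart=39_999, tEnd=40_099)
        call = amb.classify_ambiguity(
            _event(self.KEY), [self_d, self_a], _jseq(self.KEY), {"chr1"}
        )
        assert call.status == "ok" and not call.alt_flag and not call.multi_flag

    def test_no_hits_at_all_is_ok_with_zero_scores(self, caplog):
        with caplog.at_level("WARNING"):
            call = amb.classify_ambiguity(_event(self.KEY), [], _jseq(self.KEY), {"chr1"})
        assert call.status == "ok" and call.best_hit_score == 0.0

    def test_transcript_hits_do_not_feed_the_multi_hit_screen(self):
        tx1 = make_hit(matches=150, misMatches=50, tName="TXa")  # identity 0.75
        tx2 = make_hit(matches=149, misMatches=51, tName="TXb")
        call = amb.classify_ambiguity(
            _event(self.KEY), [tx1, tx2], _jseq(self.KEY), {"chr1"}
        )
        assert call.status == "ok"


class TestJunctionSequence:
    def test_donor_flank_walks_the_spliced_transcript(self, tiny_annotation, tiny_genome):
        # donor exon chr1:[4951..5000] (50 nt) is preceded by [4801..4900]:
        # the 100 nt donor flank is the last 50 nt of the upstream exon plus
        # the whole donor exon
        key = io.EventKey("chr1", 5000, "+", "chr1", 100, "+")
        event = _event(key, {"GB"}, {"GA"})
        js = amb.build_junction_sequence(event, tiny_annotation, tiny_genome)
        expected_donor = tiny_genome["chr1"][4850:4900] + tiny_genome["chr1"][4950:5000]
        assert js.donor_flank_len == 100
        assert js.sequence[:100] == expected_donor

    def test_short_circle_uses_full_circle_sequence(self, tiny_annotation, tiny_genome):
        # gene GD: exons [1000..1059] and [1200..1259] on chr2 '+': the
        # exonic circle from acceptor 1000 to donor 1259 is 120 nt
        key = io.EventKey("chr2", 1259, "+", "chr2", 1000, "+")
        js = amb.build_junction_sequence(
            _event(key, {"GD"}, {"GD"}), tiny_annotation, tiny_genome
        )
        assert len(js.sequence) == 120
        assert js.donor_flank_len + js.acceptor_flank_len == 120
        spliced = tiny_genome["chr2"][999:1059] + tiny_genome["chr2"][1199:1259]
        assert js.sequence == spliced[len(spliced) - js.donor_flank_len:] + \
            spliced[: js.acceptor_flank_len]

    def test_full_length_sequence_has_midpoint_at_100(self, tiny_annotation, tiny_genome):
        key = io.EventKey("chr1", 5000, "+", "chr1", 100, "+")
        js = amb.build_junction_sequence(
            _event(key, {"GB"}, {"GA"}), tiny_annotation, tiny_genome
        )
        assert len(js.sequence) == 200 and js.midpoint == 100

    def test_minus_strand_flank_is_reverse_complemented(self, tiny_annotation, tiny_genome):
        # gene GC on chr2 '-': donor boundary 300 (genomic start of exon
        # [300..400]); the donor flank is the reverse complement of the
        # genomic sequence downstream of it
        key = io.EventKey("chr2", 300, "-", "chr2", 400, "-")
        js = amb.build_junction_sequence(
            _event(key, {"GC"}, {"GC"}), tiny_annotation, tiny_genome
        )
        # circle: acceptor 400 .. donor 300 in transcript direction = exon
        # [300..400], 101 nt < 200 so the full circle is used
        assert len(js.sequence) == 101
        rc = str(Seq(tiny_genome["chr2"][299:400]).reverse_complement())
        d, a = js.donor_flank_len, js.acceptor_flank_len
        assert js.sequence == rc[len(rc) - d:] + rc[:a]

    def test_unannotated_junction_is_an_error(self, tiny_annotation, tiny_genome):
        key = io.EventKey("chr1", 999, "+", "chr1", 100, "+")
        with pytest.raises(ValueError):
            amb.build_junction_sequence(_event(key), tiny_annotation, tiny_genome)

    def test_fasta_export(self, tiny_annotation, tiny_genome, tmp_path):
        key = io.EventKey("chr1", 5000, "+", "chr1", 100, "+")
        js = amb.build_junction_sequence(
            _event(key, {"GB"}, {"GA"}), tiny_annotation, tiny_genome
        )
        path = tmp_path / "junctions.fa"
        amb.write_junction_fasta([js], path)
        lines = path.read_text().splitlines()
        assert lines[0] == f">{key}"
        assert "".join(lines[1:]) == js.sequence
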