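"""Boundary snapping, rejection accounting and multi-tool merging."""

import numpy as np
import pytest

from nclscreen import harmonize as hz
from nclscreen import io_formats as io


class TestSnapJunction:
    @pytest.mark.parametrize(
        "pos, boundaries, expected",
        [
            (1003, [1000, 2000], 1000),   # distance 3, inside the 5 bp rule
            (1006, [1000, 2000], None),   # distance 6, just outside
            (1005, [1000, 1010], 1000),   # tie at 5: smaller coordinate wins
            (1000, [1000, 2000], 1000),   # exact boundary is idempotent
            (1998, [1000, 2000], 2000),
            (5, [], None),
        ],
    )
    def test_examples(self, pos, boundaries, expected):
        assert hz.snap_junction(pos, np.array(boundaries, dtype=np.int64)) == expected

    def test_custom_max_dist(self):
        b = np.array([1000])
        assert hz.snap_junction(1010, b, max_dist=10) == 1000
        assert hz.snap_junction(1011, b, max_dist=10) is None


def _record(dpos, apos, n=5, dchrom="chr1", achrom="chr1", strand="+"):
    return io.RawEventRecord(dchrom, dpos, strand, achrom, apos, strand, n)


class TestHarmonizeRecord:
    def test_both_sides_snap(self, tiny_annotation):
        harmonized, reason = hz.harmonize_record(_record(403, 498), tiny_annotation)
        assert reason is None
        assert harmonized.key.donor_pos == 400
        assert harmonized.key.acceptor_pos == 500
        assert "GA" in harmonized.donor_genes

    def test_unannotated_donor_rejected(self, tiny_annotation):
        harmonized, reason = hz.harmonize_record(_record(406 + 5, 500), tiny_annotation)
        assert harmonized is None and reason == "unannotated_donor"

    def test_unannotated_acceptor_rejected(self, tiny_annotation):
        harmonized, reason = hz.harmonize_record(_record(400, 290), tiny_annotation)
        assert harmonized is None and reason == "unannotated_acceptor"

    def test_unknown_chrom_rejected(self, tiny_annotation):
        harmonized, reason = hz.harmonize_record(
            _record(400, 500, dchrom="chrX"), tiny_annotation
        )
        assert harmonized is None and reason == "unknown_chrom"

    def test_zero_count_rejected(self, tiny_annotation):
        harmonized, reason = hz.harmonize_record(_record(400, 500, n=0), tiny_annotation)
        assert harmonized is None and reason == "zero_count"

    def test_idempotent_on_snapped_coordinates(self, tiny_annotation):
        first, _ = hz.harmonize_record(_record(398, 503), tiny_annotation)
        again, _ = hz.harmonize_record(
            _record(first.key.donor_pos, first.key.acceptor_pos), tiny_annotation
        )
        assert again.key == first.key

    def test_donor_snaps_only_to_donor_type_boundaries(self, tiny_annotation):
        # 500 is an acceptor boundary on chr1 '+'; a donor at 502 must not
        # snap to it but to nothing (nearest donor boundary 600 is too far)
        harmonized, reason = hz.harmonize_record(_record(502, 300), tiny_annotation)
        assert harmonized is None and reason == "unannotated_donor"

    def test_shared_gene_means_intragenic(self, tiny_annotation):
        harmonized, _ = hz.harmonize_record(_record(400, 100), tiny_annotation)
        event = hz.NCLEvent(
            harmonized.key, {"t": 5}, harmonized.donor_genes, harmonized.acceptor_genes
        )
        assert event.locus_class == "intragenic"

    def test_distinct_genes_mean_intergenic(self, tiny_annotation):
        harmonized, _ = hz.harmonize_record(_record(400, 4801), tiny_annotation)
        event = hz.NCLEvent(
            harmonized.key, {"t": 5}, harmonized.donor_genes, harmonized.acceptor_genes
        )
        assert event.locus_class == "intergenic"


def _hrec(key, n):
    return hz.HarmonizedRecord(key, n, frozenset({"G"}), frozenset({"G"}))


K1 = io.EventKey("chr1", 400, "+", "chr1", 100, "+")
K2 = io.EventKey("chr1", 600, "+", "chr1", 300, "+")


class TestMerge:
    def test_union_of_tools(self):
        events = hz.merge_tool_reports(
            {"A": [_hrec(K1, 10)], "B": [_hrec(K1, 7), _hrec(K2, 3)]}
        )
        by_key = {ev.key: ev for ev in events}
        assert by_key[K1].per_tool_n_ncl == {"A": 10, "B": 7}
        assert by_key[K2].per_tool_n_ncl == {"B": 3}
        assert by_key[K2].n_supporting_tools == 1

    def test_duplicate_key_within_tool_sums_counts(self, caplog):
        with caplog.at_level("WARNING"):
            (event,) = hz.merge_tool_reports({"A": [_hrec(K1, 4), _hrec(K1, 6)]})
        assert event.per_tool_n_ncl == {"A": 10}
        assert any("more than once" in m for m in caplog.messages)

    def test_single_tool_input(self):
        events = hz.merge_tool_reports({"A": [_hrec(K1, 2), _hrec(K2, 9)]})
        assert all(ev.n_supporting_tools == 1 for ev in events)

    def test_no_tools_is_an_error(self):
        with pytest.raises(ValueError):
            hz.merge_tool_reports({})

    def test_merge_equals_brute_force_dictionary_union(self):
        rng = np.random.default_rng(42)
        keys = [
            io.EventKey("chr1", int(p), "+", "chr1", int(p) - 300, "+")
            for p in rng.integers(400, 1000, size=12)
        ]
        per_tool = {}
        for tool in ("A", "B", "C"):
            recs = []
            for _ in range(int(rng.integers(0, 18))):
                recs.append(_hrec(keys[int(rng.integers(len(keys)))], int(rng.integers(1, 50))))
            per_tool[tool] = recs
        expected: dict = {}
        for tool, recs in per_tool.items():
            for rec in recs:
                expected.setdefault(rec.key, {}).setdefault(tool, 0)
                expected[rec.key][tool] += rec.n_ncl
        merged = {ev.key: ev.per_tool_n_ncl for ev in hz.merge_tool_reports(per_tool)}
        assert merged == expected

    def test_conservation_of_records(self, tiny_annotation):
        records = [
            _record_at(403, 498),
            _record_at(400, 500),
            _record_at(950, 100),   # donor unannotated
            _record_at(200, 10),    # acceptor unannotated
        ]
        kept, rejected = hz.harmonize_tool_report("T", records, tiny_annotation)
        assert len(kept) + len(rejected) == len(records)
        assert len(rejected) == 2


def _record_at(dpos, apos):
    return io.RawEventRecord("chr1", dpos, "+", "chr1", apos, "+", 3)
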