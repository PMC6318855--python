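"""Result assembly, accounting, coverage summaries and CDF export."""

import numpy as np
import pandas as pd
import pytest

from nclscreen import report as rep
from nclscreen.ambiguity import AmbiguityCall
from nclscreen.evidence import JunctionEvidence
from nclscreen.harmonize import NCLEvent
from nclscreen.io_formats import EventKey
from nclscreen.metrics import MetricsRow


def _key(i):
    return EventKey("chr1", 1000 + 100 * i, "+", "chr1", 500 + 100 * i, "+")


def _event(i, tools, genes=("G1", "G1")):
    return NCLEvent(_key(i), {t: 5 for t in tools}, frozenset({genes[0]}), frozenset({genes[1]}))


def _call(i, status="ok"):
    return AmbiguityCall(_key(i), status, 100.0, 0.0, 0.0, status == "alt_colinear",
                         status == "multi_hit")


def _evidence(i):
    return JunctionEvidence(_key(i), 10, 20, "G1", "G1", {("chr1", 1, 2): 30},
                            {("chr1", 1, 2): 30}, {"G1": 30}, 0)


def _metrics(i):
    return MetricsRow(
        key=_key(i), n_tools=3, single_tool_comparison=False, median_n_ncl=5.0,
        n_ncl_detected=5.0, tau_ncl=0.2, ncl_score=1.5, r_ncl=0.25, cf=0.16,
        p_d=0.3, p_a=0.6, p_median_donor=0.3, p_median_acceptor=0.3,
        rpm_raw=0.5, rpm_mapped=0.7, tpm_donor=None, fpkm_donor=None,
        tpm_acceptor=None, fpkm_acceptor=None, sce_donor=None, sce_acceptor=None,
    )


def _tables(n, statuses, classes=None):
    events, calls, evidence, metrics = [], {}, {}, {}
    for i in range(n):
        genes = ("G1", "G1") if classes is None or classes[i] == "intragenic" else ("G1", "G2")
        ev = _event(i, ["A", "B"], genes)
        events.append(ev)
        calls[ev.key] = _call(i, statuses[i])
        evidence[ev.key] = _evidence(i)
        metrics[ev.key] = _metrics(i)
    return events, calls, evidence, metrics


class TestAssemble:
    def test_drop_ambiguous_conserves_rows(self):
        statuses = ["ok"] * 7 + ["alt_colinear", "multi_hit", "multi_hit"]
        events, calls, evidence, metrics = _tables(10, statuses)
        out = rep.assemble_results(events, calls, evidence, metrics, ["A", "B"])
        assert len(out["intragenic"]) == 7
        assert len(out["ambiguous"]) == 3

    def test_keep_all_retains_status_column(self):
        statuses = ["ok"] * 7 + ["alt_colinear", "multi_hit", "multi_hit"]
        events, calls, evidence, metrics = _tables(10, statuses)
        out = rep.assemble_results(
            events, calls, evidence, metrics, ["A", "B"], mode="keep_all"
        )
        assert len(out["intragenic"]) == 10
        assert set(out["intragenic"]["ambiguity_status"]) == {"ok", "alt_colinear", "multi_hit"}

    def test_split_by_locus_class(self):
        classes = ["intragenic", "intergenic", "intragenic"]
        events, calls, evidence, metrics = _tables(3, ["ok"] * 3, classes)
        out = rep.assemble_results(events, calls, evidence, metrics, ["A", "B"])
        assert len(out["intragenic"]) == 2 and len(out["intergenic"]) == 1

    def test_missing_metrics_key_is_a_consistency_error(self):
        events, calls, evidence, metrics = _tables(2, ["ok", "ok"])
        del metrics[events[1].key]
        with pytest.raises(ValueError, match="missing"):
            rep.assemble_results(events, calls, evidence, metrics, ["A", "B"])


class TestCoverage:
    def test_membership_and_histogram(self):
        events = [_event(0, ["A", "B"]), _event(1, ["A"])]
        calls = {ev.key: _call(i) for i, ev in enumerate(events)}
        cov = rep.coverage_summary(events, calls, ["A", "B"])
        totals = dict(zip(cov.tool_summary["tool"], cov.tool_summary["n_detected"]))
        assert totals == {"A": 2, "B": 1}
        hist = dict(
            zip(cov.support_histogram["n_supporting_tools"], cov.support_histogram["n_events"])
        )
        assert hist == {1: 1, 2: 1}
        assert (cov.membership.sum(axis=1).sort_index().values == [2, 1]).any()

    def test_row_sums_equal_supporting_tools(self, default_tree):
        _, _, result = default_tree
        cov = result.coverage
        by_key = {str(ev.key): ev.n_supporting_tools for ev in result.events}
        for key, row_sum in cov.membership.sum(axis=1).items():
            assert row_sum == by_key[key]

    def test_per_tool_ambiguous_fraction(self):
        events = [_event(i, ["A"]) for i in range(4)]
        statuses = ["multi_hit", "ok", "ok", "ok"]
        calls = {ev.key: _call(i, statuses[i]) for i, ev in enumerate(events)}
        cov = rep.coverage_summary(events, calls, ["A"])
        assert cov.tool_summary.loc[0, "ambiguous_fraction"] == pytest.approx(0.25)


class TestDistributions:
    def test_cdf_points(self):
        df = pd.DataFrame(
            {
                "donor_chrom": "chr1", "donor_pos": [1, 2, 3], "donor_strand": "+",
                "acceptor_chrom": "chr1", "acceptor_pos": [1, 2, 3],
                "acceptor_strand": "+",
                "locus_class": "intragenic", "ambiguity_status": "ok",
                "tau_ncl": [0.0, 0.5, 1.0], "ncl_score": [1.0, 1.0, 1.0],
            }
        )
        out = rep.export_distributions({"intragenic": df})
        cdf = out["cdf_tau_ncl_intragenic_nonambiguous"]
        assert list(cdf["value"]) == [0.0, 0.5, 1.0]
        assert list(cdf["cdf"]) == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_single_value_stratum(self):
        df = pd.DataFrame(
            {
                "donor_chrom": "chr1", "donor_pos": [9], "donor_strand": "+",
                "acceptor_chrom": "chr1", "acceptor_pos": [2], "acceptor_strand": "+",
                "locus_class": "intergenic", "ambiguity_status": "ok",
                "tau_ncl": [0.7], "ncl_score": [2.0],
            }
        )
        out = rep.export_distributions({"intergenic": df})
        cdf = out["cdf_tau_ncl_intergenic_nonambiguous"]
        assert cdf.shape == (1, 2) and cdf.loc[0, "cdf"] == 1.0

    def test_empty_strata_are_omitted(self):
        out = rep.export_distributions({})
        assert out == {}


class TestDeterminism:
    def test_outputs_are_byte_identical_across_runs(self, tmp_path):
        statuses = ["ok"] * 4 + ["multi_hit"]
        events, calls, evidence, metrics = _tables(5, statuses)
        for d in ("a", "b"):
            out = rep.assemble_results(events, calls, evidence, metrics, ["A", "B"])
            cov = rep.coverage_summary(events, calls, ["A", "B"])
            cdfs = rep.export_distributions(out)
            rep.write_outputs(tmp_path / d, out, cov, cdfs, [])
        for name in (tmp_path / "a").iterdir():
            assert name.read_bytes() == (tmp_path / "b" / name.name).read_bytes()
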