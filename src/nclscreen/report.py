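"""Assembly of the union result tables and summary matrices.

The screened event universe is exported as two tab-delimited tables
(intragenic and intergenic), with ambiguous events either kept (flagged) or
moved to a side table; per-tool coverage, the supporting-tool histogram and
the cumulative distributions of tau/score (for external KS tests or plots)
are emitted alongside.  Identical inputs produce byte-identical files:
events are sorted by coordinates and floats printed with six decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ambiguity import AmbiguityCall
from .evidence import JunctionEvidence
from .harmonize import NCLEvent, Rejection, write_rejections
from .io_formats import EventKey
from .metrics import MetricsRow

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6f"
SORT_COLUMNS = ["donor_chrom", "donor_pos", "acceptor_chrom", "acceptor_pos"]


def _flag(value: bool | None) -> object:
    if value is None:
        return np.nan
    return "yes" if value else "no"


def assemble_results(
    events: Sequence[NCLEvent],
    calls: Mapping[EventKey, AmbiguityCall],
    evidence: Mapping[EventKey, JunctionEvidence],
    metrics: Mapping[EventKey, MetricsRow],
    tool_order: Sequence[str],
    mode: str = "drop_ambiguous",
) -> dict[str, pd.DataFrame]:
    """Join all per-event tables into the result frames.

    Returns ``{"intragenic": df, "intergenic": df, "ambiguous": df}``.  In
    ``drop_ambiguous`` mode events with status != ok go to the side table
    only; in ``keep_all`` mode every event stays in its main table.  The
    accounting identity (before = ambiguous + after, per locus class) holds
    by construction and is asserted.
    """
    if mode not in ("drop_ambiguous", "keep_all"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for ev in events:
        key = ev.key
        for table, name in ((calls, "ambiguity"), (evidence, "evidence"), (metrics, "metrics")):
            if key not in table:
                raise ValueError(f"event {key} missing from the {name} table")
        call, evd, met = calls[key], evidence[key], metrics[key]
        row = {
            "donor_chrom": key.donor_chrom,
            "donor_pos": key.donor_pos,
            "donor_strand": key.donor_strand,
            "acceptor_chrom": key.acceptor_chrom,
            "acceptor_pos": key.acceptor_pos,
            "acceptor_strand": key.acceptor_strand,
            "locus_class": ev.locus_class,
            "donor_genes": ",".join(sorted(ev.donor_genes)) or np.nan,
            "acceptor_genes": ",".join(sorted(ev.acceptor_genes)) or np.nan,
        }
        for tool in tool_order:
            row[f"n_ncl_{tool}"] = ev.per_tool_n_ncl.get(tool, 0)
        row.update(
            n_supporting_tools=ev.n_supporting_tools,
            ambiguity_status=call.status,
            best_hit_score=call.best_hit_score,
            runner_up_score=call.runner_up_score,
            colinear_identity=call.colinear_identity,
            median_n_ncl=met.median_n_ncl,
            n_ncl_detected=met.n_ncl_detected,
            tau_ncl=met.tau_ncl,
            ncl_score=met.ncl_score,
            n_d=evd.n_d,
            n_a=evd.n_a,
            r_ncl=np.nan if met.r_ncl is None else met.r_ncl,
            cf=met.cf,
            p_d=np.nan if met.p_d is None else met.p_d,
            p_a=np.nan if met.p_a is None else met.p_a,
            p_median_donor=np.nan if met.p_median_donor is None else met.p_median_donor,
            p_median_acceptor=np.nan if met.p_median_acceptor is None else met.p_median_acceptor,
            rpm_raw=met.rpm_raw,
            rpm_mapped=met.rpm_mapped,
            tpm_donor=np.nan if met.tpm_donor is None else met.tpm_donor,
            fpkm_donor=np.nan if met.fpkm_donor is None else met.fpkm_donor,
            tpm_acceptor=np.nan if met.tpm_acceptor is None else met.tpm_acceptor,
            fpkm_acceptor=np.nan if met.fpkm_acceptor is None else met.fpkm_acceptor,
            out_of_circle_pairs=(
                np.nan if evd.out_of_circle_pairs is None else evd.out_of_circle_pairs
            ),
            sce_donor=_flag(met.sce_donor),
            sce_acceptor=_flag(met.sce_acceptor),
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        empty = df
        return {"intragenic": empty, "intergenic": empty, "ambiguous": empty}
    df = df.sort_values(SORT_COLUMNS, kind="mergesort").reset_index(drop=True)
    ambiguous = df[df["ambiguity_status"] != "ok"].reset_index(drop=True)
    main = df if mode == "keep_all" else df[df["ambiguity_status"] == "ok"].reset_index(drop=True)
    out = {
        "intragenic": main[main["locus_class"] == "intragenic"].reset_index(drop=True),
        "intergenic": main[main["locus_class"] == "intergenic"].reset_index(drop=True),
        "ambiguous": ambiguous,
    }
    if mode == "drop_ambiguous":
        for cls in ("intragenic", "intergenic"):
            before = int((df["locus_class"] == cls).sum())
            after = len(out[cls])
            amb = int((ambiguous["locus_class"] == cls).sum())
            assert before == after + amb, "accounting identity violated"
    return out


@dataclass
class CoverageMatrix:
    """Tool-membership matrix and derived per-tool / per-event summaries."""

    membership: pd.DataFrame        # events x tools, 0/1
    tool_summary: pd.DataFrame      # per tool: totals, tool-specific, ambiguous counts
    support_histogram: pd.DataFrame  # k tools -> event count and fraction


def coverage_summary(
    events: Sequence[NCLEvent],
    calls: Mapping[EventKey, AmbiguityCall],
    tool_order: Sequence[str],
) -> CoverageMatrix:
    if not events:
        raise ValueError("coverage summary needs at least one event")
    keys = [str(ev.key) for ev in events]
    membership = pd.DataFrame(
        [[1 if t in ev.per_tool_n_ncl else 0 for t in tool_order] for ev in events],
        index=keys,
        columns=list(tool_order),
    ).sort_index()
    support = membership.sum(axis=1)
    hist = support.value_counts().sort_index()
    support_histogram = pd.DataFrame(
        {
            "n_supporting_tools": hist.index.astype(int),
            "n_events": hist.values,
            "fraction": hist.values / len(events),
        }
    )
    rows = []
    for tool in tool_order:
        detected = [ev for ev in events if tool in ev.per_tool_n_ncl]
        n_detected = len(detected)
        n_specific = sum(1 for ev in detected if ev.n_supporting_tools == 1)
        n_alt = sum(1 for ev in detected if calls[ev.key].status == "alt_colinear")
        n_multi = sum(1 for ev in detected if calls[ev.key].status == "multi_hit")
        rows.append(
            {
                "tool": tool,
                "n_detected": n_detected,
                "n_tool_specific": n_specific,
                "n_alt_colinear": n_alt,
                "n_multi_hit": n_multi,
                "ambiguous_fraction": (
                    (n_alt + n_multi) / n_detected if n_detected else np.nan
                ),
            }
        )
    return CoverageMatrix(membership, pd.DataFrame(rows), support_histogram)


def export_distributions(
    results: Mapping[str, pd.DataFrame], columns: Sequence[str] = ("tau_ncl", "ncl_score")
) -> dict[str, pd.DataFrame]:
    """Empirical cumulative distributions of the given metric columns, split
    by locus class and ambiguity group (non-ambiguous vs ambiguous).

    Returns ``{"cdf_<metric>_<class>_<group>": DataFrame(value, cdf)}``;
    empty strata are omitted with a warning.
    """
    frames = []
    for name in ("intragenic", "intergenic"):
        df = results.get(name)
        if df is not None and not df.empty:
            frames.append(df)
    amb = results.get("ambiguous")
    if amb is not None and not amb.empty:
        frames.append(amb)
    if not frames:
        return {}
    full = pd.concat(frames, ignore_index=True)
    full = full.drop_duplicates(
        subset=SORT_COLUMNS + ["donor_strand", "acceptor_strand"]
    )
    out: dict[str, pd.DataFrame] = {}
    for metric in columns:
        for cls in ("intragenic", "intergenic"):
            for group, selector in (
                ("nonambiguous", full["ambiguity_status"] == "ok"),
                ("ambiguous", full["ambiguity_status"] != "ok"),
            ):
                values = full.loc[(full["locus_class"] == cls) & selector, metric]
                values = values.dropna().to_numpy(dtype=float)
                stratum = f"cdf_{metric}_{cls}_{group}"
                if values.size == 0:
                    logger.warning("stratum %s is empty; omitted", stratum)
                    continue
                uniq, counts = np.unique(values, return_counts=True)
                cdf = np.cumsum(counts) / values.size
                out[stratum] = pd.DataFrame({"value": uniq, "cdf": cdf})
    return out


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="NA")


def write_outputs(
    outdir: str | Path,
    results: Mapping[str, pd.DataFrame],
    coverage: CoverageMatrix,
    cdfs: Mapping[str, pd.DataFrame],
    rejections: Sequence[Rejection],
) -> None:
    """Write all result and summary tables under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("intragenic", "intergenic", "ambiguous"):
        _write_tsv(results[name], outdir / f"{name}.tsv")
    write_rejections(rejections, outdir / "rejected.tsv")
    membership = coverage.membership.copy()
    membership.insert(0, "event", membership.index)
    _write_tsv(membership.reset_index(drop=True), outdir / "coverage_matrix.tsv")
    _write_tsv(coverage.tool_summary, outdir / "tool_summary.tsv")
    _write_tsv(coverage.support_histogram, outdir / "support_histogram.tsv")
    for name, df in sorted(cdfs.items()):
        _write_tsv(df, outdir / f"{name}.tsv")


def plot_summaries(outdir: str | Path, coverage: CoverageMatrix) -> bool:
    """Optional coverage figures; returns False when no plotting backend is
    available.  The TSV matrices, not the figures, are the contract."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        logger.warning("matplotlib unavailable; skipping figures")
        return False
    outdir = Path(outdir)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    ts = coverage.tool_summary
    axes[0].bar(ts["tool"], ts["n_detected"], label="detected")
    axes[0].bar(ts["tool"], ts["n_tool_specific"], label="tool-specific")
    axes[0].set_ylabel("NCL events")
    axes[0].tick_params(axis="x", rotation=90)
    axes[0].legend()
    sh = coverage.support_histogram
    axes[1].bar(sh["n_supporting_tools"], sh["n_events"])
    axes[1].set_xlabel("supporting tools")
    axes[1].set_ylabel("NCL events")
    fig.tight_layout()
    fig.savefig(outdir / "coverage_summary.png", dpi=150)
    plt.close(fig)
    return True
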