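"""Snap detector-reported junctions to annotated exon boundaries and merge
per-tool reports into one event universe.

Detectors disagree by a few bases around splice sites; a reported junction is
accepted when it lies within ``max_dist`` (default 5 bp) of an annotated
boundary of the matching type (donor coordinates snap only to donor-type
boundaries, i.e. transcript-direction exon ends), and its coordinate is
adjusted to that boundary.  Events failing to snap on either side are
rejected and accounted for in an audit table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import AnnotationIndex, EventKey, RawEventRecord

logger = logging.getLogger(__name__)

DEFAULT_SNAP_DIST = 5


def snap_junction(
    pos: int, boundaries: np.ndarray, max_dist: int = DEFAULT_SNAP_DIST
) -> int | None:
    """Nearest annotated boundary within ``max_dist`` of ``pos``.

    Ties at equal distance break toward the smaller genomic coordinate.
    Returns ``None`` when no boundary is close enough.
    """
    if len(boundaries) == 0:
        return None
    i = int(np.searchsorted(boundaries, pos))
    best: int | None = None
    best_dist = max_dist + 1
    # candidate on the left first so that equal distance keeps the smaller one
    for j in (i - 1, i):
        if 0 <= j < len(boundaries):
            cand = int(boundaries[j])
            dist = abs(cand - pos)
            if dist < best_dist:
                best, best_dist = cand, dist
    return best


@dataclass(frozen=True)
class HarmonizedRecord:
    """A detector record whose both junctions snapped to annotated boundaries."""

    key: EventKey
    n_ncl: int
    donor_genes: frozenset[str]
    acceptor_genes: frozenset[str]


@dataclass(frozen=True)
class Rejection:
    tool: str
    record: RawEventRecord
    reason: str  # unknown_chrom | unannotated_donor | unannotated_acceptor | zero_count


def harmonize_record(
    record: RawEventRecord,
    annotation: AnnotationIndex,
    max_dist: int = DEFAULT_SNAP_DIST,
) -> tuple[HarmonizedRecord | None, str | None]:
    """Snap one record; returns (harmonized, None) or (None, reason)."""
    if (
        record.donor_chrom not in annotation.chroms
        or record.acceptor_chrom not in annotation.chroms
    ):
        return None, "unknown_chrom"
    if record.n_ncl == 0:
        return None, "zero_count"
    donor = snap_junction(
        record.donor_pos,
        annotation.donor_positions(record.donor_chrom, record.donor_strand),
        max_dist,
    )
    if donor is None:
        return None, "unannotated_donor"
    acceptor = snap_junction(
        record.acceptor_pos,
        annotation.acceptor_positions(record.acceptor_chrom, record.acceptor_strand),
        max_dist,
    )
    if acceptor is None:
        return None, "unannotated_acceptor"
    key = EventKey(
        record.donor_chrom, donor, record.donor_strand,
        record.acceptor_chrom, acceptor, record.acceptor_strand,
    )
    donor_genes = frozenset(
        g for g, _ in annotation.donor_owners(key.donor_chrom, key.donor_strand, donor)
    )
    acceptor_genes = frozenset(
        g for g, _ in annotation.acceptor_owners(key.acceptor_chrom, key.acceptor_strand, acceptor)
    )
    return HarmonizedRecord(key, record.n_ncl, donor_genes, acceptor_genes), None


def harmonize_tool_report(
    tool: str,
    records: Iterable[RawEventRecord],
    annotation: AnnotationIndex,
    max_dist: int = DEFAULT_SNAP_DIST,
) -> tuple[list[HarmonizedRecord], list[Rejection]]:
    kept: list[HarmonizedRecord] = []
    rejected: list[Rejection] = []
    for rec in records:
        harmonized, reason = harmonize_record(rec, annotation, max_dist)
        if harmonized is None:
            rejected.append(Rejection(tool, rec, reason or "unknown"))
        else:
            kept.append(harmonized)
    return kept, rejected


@dataclass
class NCLEvent:
    """A harmonized NCL junction with its per-tool junction read counts."""

    key: EventKey
    per_tool_n_ncl: dict[str, int] = field(default_factory=dict)
    donor_genes: frozenset[str] = frozenset()
    acceptor_genes: frozenset[str] = frozenset()

    @property
    def locus_class(self) -> str:
        return "intragenic" if self.donor_genes & self.acceptor_genes else "intergenic"

    @property
    def n_supporting_tools(self) -> int:
        return len(self.per_tool_n_ncl)


def merge_tool_reports(
    per_tool: Mapping[str, Sequence[HarmonizedRecord]],
) -> list[NCLEvent]:
    """Union of the harmonized events across tools, grouped by snapped key.

    A tool reporting the same key more than once has its counts summed (with
    a warning).  Events are returned sorted by key for deterministic output.
    """
    if not per_tool:
        raise ValueError("at least one tool report is required")
    events: dict[EventKey, NCLEvent] = {}
    for tool in per_tool:
        for rec in per_tool[tool]:
            ev = events.get(rec.key)
            if ev is None:
                ev = events[rec.key] = NCLEvent(
                    rec.key, {}, rec.donor_genes, rec.acceptor_genes
                )
            else:
                ev.donor_genes |= rec.donor_genes
                ev.acceptor_genes |= rec.acceptor_genes
            if tool in ev.per_tool_n_ncl:
                logger.warning(
                    "tool %s reported event %s more than once; counts summed",
                    tool, rec.key,
                )
                ev.per_tool_n_ncl[tool] += rec.n_ncl
            else:
                ev.per_tool_n_ncl[tool] = rec.n_ncl
    if not events:
        logger.warning("no events survived harmonization")
    return [events[k] for k in sorted(events)]


def write_rejections(rejections: Iterable[Rejection], path: str | Path) -> None:
    """Audit TSV of rejected records (tool, raw coordinates, reason)."""
    with open(path, "w") as fh:
        fh.write(
            "tool\tdonor_chrom\tdonor_pos\tdonor_strand\t"
            "acceptor_chrom\tacceptor_pos\tacceptor_strand\tn_ncl\treason\n"
        )
        for r in rejections:
            rec = r.record
            fh.write(
                f"{r.tool}\t{rec.donor_chrom}\t{rec.donor_pos}\t{rec.donor_strand}\t"
                f"{rec.acceptor_chrom}\t{rec.acceptor_pos}\t{rec.acceptor_strand}\t"
                f"{rec.n_ncl}\t{r.reason}\n"
            )
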