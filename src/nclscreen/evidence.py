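"""Co-linear junction read evidence around NCL junctions.

``N_D`` / ``N_A`` count the uniquely-mapping reads spanning the annotated
co-linear splice junctions adjacent to the NCL donor / acceptor boundary
(all annotated introns leaving the boundary, deduplicated by coordinates);
per-host-gene totals over every annotated junction feed the usage
frequencies; and for intragenic events the number of read pairs with one
read on the NCL junction and the mate aligned entirely outside the putative
circle distinguishes trans-splicing from circRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .harmonize import NCLEvent
from .io_formats import AnnotationIndex, ChimericRecord, SpliceJunctionCount


def build_sj_index(
    sj_counts: Iterable[SpliceJunctionCount],
) -> dict[tuple[str, int, int], int]:
    """Index unique read counts by (chrom, intron_start, intron_end); counts
    of duplicate records are summed."""
    index: dict[tuple[str, int, int], int] = {}
    for rec in sj_counts:
        key = (rec.chrom, rec.intron_start, rec.intron_end)
        index[key] = index.get(key, 0) + rec.unique_read_count
    return index


@dataclass
class JunctionEvidence:
    """Per-event co-linear evidence (counts of Fig-style D/A junctions)."""

    key: object
    n_d: int
    n_a: int
    donor_gene: str | None
    acceptor_gene: str | None
    donor_gene_junction_counts: dict[tuple[str, int, int], int] = field(default_factory=dict)
    acceptor_gene_junction_counts: dict[tuple[str, int, int], int] = field(default_factory=dict)
    gene_junction_totals: dict[str, int] = field(default_factory=dict)
    out_of_circle_pairs: int | None = None


def _host_gene(genes: frozenset[str], shared: frozenset[str]) -> str | None:
    pool = shared or genes
    return min(pool) if pool else None


def gene_junction_counts(
    gene_id: str,
    sj_index: Mapping[tuple[str, int, int], int],
    annotation: AnnotationIndex,
) -> dict[tuple[str, int, int], int]:
    """Unique read count of every annotated junction of a gene (0 when the
    junction has no record)."""
    return {
        intron: sj_index.get(intron, 0)
        for intron in sorted(annotation.gene_introns(gene_id))
    }


def count_junction_reads(
    event: NCLEvent,
    sj_index: Mapping[tuple[str, int, int], int],
    annotation: AnnotationIndex,
) -> JunctionEvidence:
    """Count N_D, N_A and host-gene junction totals for one event."""
    key = event.key
    donor_introns = annotation.donor_adjacent_introns(
        key.donor_chrom, key.donor_strand, key.donor_pos
    )
    acceptor_introns = annotation.acceptor_adjacent_introns(
        key.acceptor_chrom, key.acceptor_strand, key.acceptor_pos
    )
    n_d = sum(sj_index.get((key.donor_chrom,) + i, 0) for i in sorted(donor_introns))
    n_a = sum(sj_index.get((key.acceptor_chrom,) + i, 0) for i in sorted(acceptor_introns))
    shared = event.donor_genes & event.acceptor_genes
    donor_gene = _host_gene(event.donor_genes, frozenset(shared))
    acceptor_gene = _host_gene(event.acceptor_genes, frozenset(shared))
    totals: dict[str, int] = {}
    for gene in sorted(event.donor_genes | event.acceptor_genes):
        totals[gene] = sum(
            gene_junction_counts(gene, sj_index, annotation).values()
        )
    return JunctionEvidence(
        key=key,
        n_d=n_d,
        n_a=n_a,
        donor_gene=donor_gene,
        acceptor_gene=acceptor_gene,
        donor_gene_junction_counts=(
            gene_junction_counts(donor_gene, sj_index, annotation) if donor_gene else {}
        ),
        acceptor_gene_junction_counts=(
            gene_junction_counts(acceptor_gene, sj_index, annotation) if acceptor_gene else {}
        ),
        gene_junction_totals=totals,
    )


def count_out_of_circle_pairs(
    event: NCLEvent, chimeric_records: Sequence[ChimericRecord]
) -> int:
    """Read pairs supporting the NCL junction whose mate lies entirely
    outside the circle interval (or on another chromosome).

    Defined for intragenic events only; the circle interval is the closed
    genomic span between the acceptor and donor boundaries.
    """
    if event.locus_class != "intragenic":
        raise ValueError("out-of-circle pairs are defined for intragenic events only")
    key = event.key
    lo = min(key.donor_pos, key.acceptor_pos)
    hi = max(key.donor_pos, key.acceptor_pos)
    outside_reads: set[str] = set()
    for rec in chimeric_records:
        if (
            rec.donor_chrom != key.donor_chrom
            or rec.donor_pos != key.donor_pos
            or rec.donor_strand != key.donor_strand
            or rec.acceptor_chrom != key.acceptor_chrom
            or rec.acceptor_pos != key.acceptor_pos
            or rec.acceptor_strand != key.acceptor_strand
        ):
            continue
        if rec.mate_chrom != key.donor_chrom:
            outside_reads.add(rec.read_id)
        elif rec.mate_end < lo or rec.mate_start > hi:
            # the mate must fall entirely outside the closed circle interval
            outside_reads.add(rec.read_id)
    return len(outside_reads)


def compute_rpm(
    count: float, total_raw_reads: int, total_mapped_reads: int
) -> tuple[float, float]:
    """Reads per million raw reads and per million uniquely mapped reads."""
    if total_raw_reads <= 0 or total_mapped_reads <= 0:
        raise ValueError("library sizes must be positive")
    return (
        count * 1e6 / total_raw_reads,
        count * 1e6 / total_mapped_reads,
    )


def collect_evidence(
    event: NCLEvent,
    sj_index: Mapping[tuple[str, int, int], int],
    annotation: AnnotationIndex,
    chimeric_records: Sequence[ChimericRecord],
) -> JunctionEvidence:
    """Full evidence for one event (out-of-circle pairs for intragenic only)."""
    ev = count_junction_reads(event, sj_index, annotation)
    if event.locus_class == "intragenic":
        ev.out_of_circle_pairs = count_out_of_circle_pairs(event, chimeric_records)
    return ev
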