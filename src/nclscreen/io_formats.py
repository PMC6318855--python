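"""Readers and writers for the text formats the screening pipeline touches.

Every reader normalizes coordinates at the boundary: internally all positions
are 1-based inclusive.  A non-co-linear (NCL) junction is described by a donor
side (last exonic base of the donor segment, in transcript direction) and an
acceptor side (first exonic base of the acceptor segment).  Supported formats:

* per-detector NCL event tables (tab-delimited, declarative column maps),
* gene annotation (GTF with exon features, via :mod:`gffutils`),
* BLAT PSL alignments (21-column, optional 5-line header),
* splice-junction read counts (STAR ``SJ.out.tab`` dialect),
* chimeric junction-spanning read records (STAR ``Chimeric.out.junction``
  dialect),
* SCE intervals (BED) and gene quantification (RSEM ``*.genes.results``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: the seven column roles every detector table must map
EVENT_ROLES = (
    "donor_chrom",
    "donor_pos",
    "donor_strand",
    "acceptor_chrom",
    "acceptor_pos",
    "acceptor_strand",
    "n_ncl",
)


class FormatError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


class EventKey(NamedTuple):
    """Harmonized identity of an NCL junction (1-based exonic boundary bases)."""

    donor_chrom: str
    donor_pos: int
    donor_strand: str
    acceptor_chrom: str
    acceptor_pos: int
    acceptor_strand: str

    def __str__(self) -> str:
        return (
            f"{self.donor_chrom}:{self.donor_pos}:{self.donor_strand}"
            f"|{self.acceptor_chrom}:{self.acceptor_pos}:{self.acceptor_strand}"
        )

    @classmethod
    def parse(cls, text: str) -> "EventKey":
        donor, acceptor = text.split("|")
        dc, dp, ds = donor.rsplit(":", 2)
        ac, ap, as_ = acceptor.rsplit(":", 2)
        return cls(dc, int(dp), ds, ac, int(ap), as_)


@dataclass(frozen=True)
class RawEventRecord:
    """One detector-reported NCL event, normalized to 1-based coordinates."""

    donor_chrom: str
    donor_pos: int
    donor_strand: str
    acceptor_chrom: str
    acceptor_pos: int
    acceptor_strand: str
    n_ncl: int

    def __post_init__(self) -> None:
        if self.n_ncl < 0:
            raise ValueError(f"n_ncl must be >= 0, got {self.n_ncl}")
        if self.donor_strand not in STRANDS or self.acceptor_strand not in STRANDS:
            raise ValueError("strands must be '+' or '-'")
        if self.donor_pos < 1 or self.acceptor_pos < 1:
            raise ValueError("positions must be >= 1")


@dataclass
class ToolConfig:
    """Declarative description of one detector's output table.

    ``column_map`` maps each role in :data:`EVENT_ROLES` to a 0-based column
    index.  ``coordinate_base`` is 0 or 1.  For 0-based dialects each position
    field is declared *start-like* (0-based start: shift +1 to reach the
    1-based base) or *end-like* (0-based end-exclusive: numerically equal to
    the 1-based last base, no shift).
    """

    tool_name: str
    path: str | Path
    column_map: Mapping[str, int]
    coordinate_base: int = 1
    has_header: bool = False
    scope: str = "both"  # intragenic | intergenic | both
    zero_based_kind: Mapping[str, str] = field(
        default_factory=lambda: {"donor_pos": "end_like", "acceptor_pos": "start_like"}
    )

    def __post_init__(self) -> None:
        missing = set(EVENT_ROLES) - set(self.column_map)
        if missing:
            raise ValueError(f"tool {self.tool_name}: unmapped roles {sorted(missing)}")
        idx = [self.column_map[r] for r in EVENT_ROLES]
        if len(set(idx)) != len(idx):
            raise ValueError(f"tool {self.tool_name}: column indices must be distinct")
        if self.coordinate_base not in (0, 1):
            raise ValueError("coordinate_base must be 0 or 1")
        if self.scope not in ("intragenic", "intergenic", "both"):
            raise ValueError(f"tool {self.tool_name}: bad scope {self.scope!r}")


def read_tool_events(config: ToolConfig) -> list[RawEventRecord]:
    """Parse one detector table into normalized event records."""
    path = Path(config.path)
    records: list[RawEventRecord] = []
    need = max(config.column_map.values()) + 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if config.has_header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < need:
                raise FormatError(
                    f"tool {config.tool_name}, row {lineno}: expected >= {need} "
                    f"columns, found {len(fields)}"
                )
            raw = {role: fields[config.column_map[role]] for role in EVENT_ROLES}
            try:
                n_ncl = int(raw["n_ncl"])
            except ValueError as exc:
                raise FormatError(
                    f"tool {config.tool_name}, row {lineno}: non-integer "
                    f"junction read count {raw['n_ncl']!r}"
                ) from exc
            try:
                dpos = _to_one_based(int(raw["donor_pos"]), "donor_pos", config)
                apos = _to_one_based(int(raw["acceptor_pos"]), "acceptor_pos", config)
                records.append(
                    RawEventRecord(
                        donor_chrom=raw["donor_chrom"],
                        donor_pos=dpos,
                        donor_strand=raw["donor_strand"],
                        acceptor_chrom=raw["acceptor_chrom"],
                        acceptor_pos=apos,
                        acceptor_strand=raw["acceptor_strand"],
                        n_ncl=n_ncl,
                    )
                )
            except ValueError as exc:
                raise FormatError(
                    f"tool {config.tool_name}, row {lineno}: {exc}"
                ) from exc
    return records


def _to_one_based(pos: int, role: str, config: ToolConfig) -> int:
    if config.coordinate_base == 1:
        return pos
    kind = config.zero_based_kind.get(role, "start_like")
    return pos + 1 if kind == "start_like" else pos


def write_tool_events(
    records: Iterable[RawEventRecord], path: str | Path, header: bool = True
) -> None:
    """Write records in the canonical 1-based 7-column dialect (paired reader:
    :func:`read_tool_events` with an identity column map)."""
    with open(path, "w") as fh:
        if header:
            fh.write("\t".join(EVENT_ROLES) + "\n")
        for r in records:
            fh.write(
                f"{r.donor_chrom}\t{r.donor_pos}\t{r.donor_strand}\t"
                f"{r.acceptor_chrom}\t{r.acceptor_pos}\t{r.acceptor_strand}\t"
                f"{r.n_ncl}\n"
            )


def canonical_tool_config(tool_name: str, path: str | Path, scope: str = "both") -> ToolConfig:
    """ToolConfig for tables written by :func:`write_tool_events`."""
    return ToolConfig(
        tool_name=tool_name,
        path=path,
        column_map={role: i for i, role in enumerate(EVENT_ROLES)},
        coordinate_base=1,
        has_header=True,
        scope=scope,
    )


# ---------------------------------------------------------------------------
# annotation


@dataclass
class Transcript:
    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic ascending, 1-based inclusive


@dataclass
class Gene:
    id: str
    name: str
    chrom: str
    strand: str
    start: int
    end: int


class AnnotationIndex:
    """Exon-boundary and intron indexes built from a GTF.

    Donor boundaries are transcript-direction exon *ends* (genomic end on '+',
    genomic start on '-'); acceptor boundaries are transcript-direction exon
    *starts*.  Boundaries are stored as genomic positions keyed by
    (chrom, strand).  Introns (first..last intronic base) are indexed by the
    exonic boundary they are adjacent to, and per gene.
    """

    def __init__(self) -> None:
        self.genes: dict[str, Gene] = {}
        self.transcripts: dict[str, Transcript] = {}
        self._donor_owners: dict[tuple[str, str, int], set[tuple[str, str]]] = {}
        self._acceptor_owners: dict[tuple[str, str, int], set[tuple[str, str]]] = {}
        self._donor_sorted: dict[tuple[str, str], np.ndarray] = {}
        self._acceptor_sorted: dict[tuple[str, str], np.ndarray] = {}
        self._donor_introns: dict[tuple[str, str, int], set[tuple[int, int]]] = {}
        self._acceptor_introns: dict[tuple[str, str, int], set[tuple[int, int]]] = {}
        self._gene_introns: dict[str, set[tuple[str, int, int]]] = {}
        self.chroms: set[str] = set()

    # -- construction -------------------------------------------------------

    def _add_transcript(self, tx: Transcript, gene_name: str) -> None:
        self.transcripts[tx.id] = tx
        self.chroms.add(tx.chrom)
        gene = self.genes.get(tx.gene_id)
        start, end = tx.exons[0][0], tx.exons[-1][1]
        if gene is None:
            self.genes[tx.gene_id] = Gene(
                tx.gene_id, gene_name, tx.chrom, tx.strand, start, end
            )
        else:
            gene.start = min(gene.start, start)
            gene.end = max(gene.end, end)
        owner = (tx.gene_id, tx.id)
        for s, e in tx.exons:
            dpos = e if tx.strand == "+" else s
            apos = s if tx.strand == "+" else e
            self._donor_owners.setdefault((tx.chrom, tx.strand, dpos), set()).add(owner)
            self._acceptor_owners.setdefault((tx.chrom, tx.strand, apos), set()).add(owner)
        introns = self._gene_introns.setdefault(tx.gene_id, set())
        for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
            if s2 <= e1 + 1:  # abutting or overlapping exons: no intron
                continue
            intron = (e1 + 1, s2 - 1)
            introns.add((tx.chrom,) + intron)
            if tx.strand == "+":
                dkey, akey = (tx.chrom, "+", e1), (tx.chrom, "+", s2)
            else:
                dkey, akey = (tx.chrom, "-", s2), (tx.chrom, "-", e1)
            self._donor_introns.setdefault(dkey, set()).add(intron)
            self._acceptor_introns.setdefault(akey, set()).add(intron)

    def _finalize(self) -> None:
        for owners, sorted_ in (
            (self._donor_owners, self._donor_sorted),
            (self._acceptor_owners, self._acceptor_sorted),
        ):
            per: dict[tuple[str, str], list[int]] = {}
            for chrom, strand, pos in owners:
                per.setdefault((chrom, strand), []).append(pos)
            for k, positions in per.items():
                sorted_[k] = np.array(sorted(positions), dtype=np.int64)

    # -- queries ------------------------------------------------------------

    def donor_positions(self, chrom: str, strand: str) -> np.ndarray:
        return self._donor_sorted.get((chrom, strand), np.empty(0, dtype=np.int64))

    def acceptor_positions(self, chrom: str, strand: str) -> np.ndarray:
        return self._acceptor_sorted.get((chrom, strand), np.empty(0, dtype=np.int64))

    def donor_owners(self, chrom: str, strand: str, pos: int) -> set[tuple[str, str]]:
        return self._donor_owners.get((chrom, strand, pos), set())

    def acceptor_owners(self, chrom: str, strand: str, pos: int) -> set[tuple[str, str]]:
        return self._acceptor_owners.get((chrom, strand, pos), set())

    def donor_adjacent_introns(self, chrom: str, strand: str, pos: int) -> set[tuple[int, int]]:
        """Annotated introns whose donor-side exonic boundary is ``pos``."""
        return self._donor_introns.get((chrom, strand, pos), set())

    def acceptor_adjacent_introns(self, chrom: str, strand: str, pos: int) -> set[tuple[int, int]]:
        return self._acceptor_introns.get((chrom, strand, pos), set())

    def gene_introns(self, gene_id: str) -> set[tuple[str, int, int]]:
        """Deduplicated (chrom, start, end) introns of a gene."""
        return self._gene_introns.get(gene_id, set())


def read_annotation(gtf_path: str | Path) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from GTF exon features."""
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    by_tx: dict[str, Transcript] = {}
    names: dict[str, str] = {}
    n_exons = 0
    for ex in db.features_of_type("exon"):
        try:
            tx_id = ex.attributes["transcript_id"][0]
            gene_id = ex.attributes["gene_id"][0]
        except KeyError:
            logger.warning("exon at %s:%d-%d lacks transcript_id/gene_id; skipped",
                           ex.seqid, ex.start, ex.end)
            continue
        n_exons += 1
        names.setdefault(gene_id, ex.attributes.get("gene_name", [gene_id])[0])
        tx = by_tx.get(tx_id)
        if tx is None:
            by_tx[tx_id] = Transcript(tx_id, gene_id, ex.seqid, ex.strand, [(ex.start, ex.end)])
        else:
            tx.exons.append((ex.start, ex.end))
    if n_exons == 0:
        raise FormatError(f"{gtf_path}: no exon features with transcript_id found")
    index = AnnotationIndex()
    for tx_id in sorted(by_tx):
        tx = by_tx[tx_id]
        tx.exons.sort()
        index._add_transcript(tx, names[tx.gene_id])
    index._finalize()
    return index


# ---------------------------------------------------------------------------
# PSL


@dataclass(frozen=True)
class PSLHit:
    """One BLAT alignment line (PSL 21-column; q/t coordinates 0-based half-open)."""

    matches: int
    misMatches: int
    repMatches: int
    nCount: int
    qNumInsert: int
    qBaseInsert: int
    tNumInsert: int
    tBaseInsert: int
    strand: str
    qName: str
    qSize: int
    qStart: int
    qEnd: int
    tName: str
    tSize: int
    tStart: int
    tEnd: int
    blockCount: int
    blockSizes: tuple[int, ...]
    qStarts: tuple[int, ...]
    tStarts: tuple[int, ...]


def _int_list(text: str) -> tuple[int, ...]:
    return tuple(int(x) for x in text.rstrip(",").split(",") if x)


def read_psl(path: str | Path) -> list[PSLHit]:
    """Read a PSL file, auto-skipping the optional 5-line header."""
    hits: list[PSLHit] = []
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    if lines and lines[0].startswith("psLayout"):
        start = 5
    for lineno, line in enumerate(lines[start:], start=start + 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 21:
            raise FormatError(f"{path}, line {lineno}: expected 21 PSL columns, found {len(fields)}")
        hit = PSLHit(
            matches=int(fields[0]),
            misMatches=int(fields[1]),
            repMatches=int(fields[2]),
            nCount=int(fields[3]),
            qNumInsert=int(fields[4]),
            qBaseInsert=int(fields[5]),
            tNumInsert=int(fields[6]),
            tBaseInsert=int(fields[7]),
            strand=fields[8],
            qName=fields[9],
            qSize=int(fields[10]),
            qStart=int(fields[11]),
            qEnd=int(fields[12]),
            tName=fields[13],
            tSize=int(fields[14]),
            tStart=int(fields[15]),
            tEnd=int(fields[16]),
            blockCount=int(fields[17]),
            blockSizes=_int_list(fields[18]),
            qStarts=_int_list(fields[19]),
            tStarts=_int_list(fields[20]),
        )
        if len(hit.blockSizes) != hit.blockCount:
            raise FormatError(f"{path}, line {lineno}: blockSizes length != blockCount")
        hits.append(hit)
    return hits


def write_psl(hits: Iterable[PSLHit], path: str | Path) -> None:
    def fmt(values: Sequence[int]) -> str:
        return ",".join(str(v) for v in values) + ","

    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.matches, h.misMatches, h.repMatches, h.nCount,
                        h.qNumInsert, h.qBaseInsert, h.tNumInsert, h.tBaseInsert,
                        h.strand, h.qName, h.qSize, h.qStart, h.qEnd,
                        h.tName, h.tSize, h.tStart, h.tEnd, h.blockCount,
                    )
                )
                + f"\t{fmt(h.blockSizes)}\t{fmt(h.qStarts)}\t{fmt(h.tStarts)}\n"
            )


# ---------------------------------------------------------------------------
# splice-junction counts and chimeric records


@dataclass(frozen=True)
class SpliceJunctionCount:
    chrom: str
    intron_start: int  # first intronic base, 1-based
    intron_end: int    # last intronic base, 1-based
    strand: str        # '+', '-' or 'undetermined'
    unique_read_count: int


_SJ_STRAND = {0: "undetermined", 1: "+", 2: "-"}
_SJ_STRAND_CODE = {v: k for k, v in _SJ_STRAND.items()}


def read_sj(path: str | Path) -> list[SpliceJunctionCount]:
    """Read the 9-column splice-junction count dialect (STAR ``SJ.out.tab``).

    Only the uniquely-mapping read count (column 7) is retained.
    """
    out: list[SpliceJunctionCount] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}, line {lineno}: expected 9 columns, found {len(f)}")
            try:
                strand = _SJ_STRAND[int(f[3])]
                rec = SpliceJunctionCount(f[0], int(f[1]), int(f[2]), strand, int(f[6]))
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
            if rec.intron_start > rec.intron_end or rec.unique_read_count < 0:
                raise FormatError(f"{path}, line {lineno}: malformed junction record")
            out.append(rec)
    return out


def write_sj(records: Iterable[SpliceJunctionCount], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.intron_start}\t{r.intron_end}\t"
                f"{_SJ_STRAND_CODE[r.strand]}\t0\t1\t{r.unique_read_count}\t0\t30\n"
            )


@dataclass(frozen=True)
class ChimericRecord:
    """One chimeric junction-spanning read pair record.

    Junction coordinates are exonic-side bases (converted from the
    intron-side convention of the STAR dialect using the strand).  The mate
    alignment interval is 1-based inclusive on the donor chromosome.
    """

    donor_chrom: str
    donor_pos: int
    donor_strand: str
    acceptor_chrom: str
    acceptor_pos: int
    acceptor_strand: str
    read_id: str
    mate_chrom: str
    mate_start: int
    mate_end: int


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_CIGAR_REF_OPS = frozenset("MDN=X")


def cigar_reference_span(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string."""
    span = 0
    for n, op in _CIGAR_RE.findall(cigar):
        if op in _CIGAR_REF_OPS:
            span += int(n)
    return span


def _intron_to_exonic(pos: int, strand: str, side: str) -> int:
    # STAR reports the first intronic base past the junction on each side.
    if side == "donor":
        return pos - 1 if strand == "+" else pos + 1
    return pos + 1 if strand == "+" else pos - 1


def _exonic_to_intron(pos: int, strand: str, side: str) -> int:
    if side == "donor":
        return pos + 1 if strand == "+" else pos - 1
    return pos - 1 if strand == "+" else pos + 1


def read_chimeric(path: str | Path) -> list[ChimericRecord]:
    """Read the 14-column chimeric junction dialect (STAR ``Chimeric.out.junction``).

    The mate alignment is taken from the second-segment columns (13/14, start
    position + CIGAR) on the donor chromosome.
    """
    out: list[ChimericRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 14:
                raise FormatError(f"{path}, line {lineno}: expected 14 columns, found {len(f)}")
            try:
                mate_start = int(f[12])
                mate_end = mate_start + cigar_reference_span(f[13]) - 1
                rec = ChimericRecord(
                    donor_chrom=f[0],
                    donor_pos=_intron_to_exonic(int(f[1]), f[2], "donor"),
                    donor_strand=f[2],
                    acceptor_chrom=f[3],
                    acceptor_pos=_intron_to_exonic(int(f[4]), f[5], "acceptor"),
                    acceptor_strand=f[5],
                    read_id=f[9],
                    mate_chrom=f[0],
                    mate_start=mate_start,
                    mate_end=mate_end,
                )
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
            if rec.donor_pos < 1 or rec.acceptor_pos < 1 or rec.mate_start < 1:
                raise FormatError(f"{path}, line {lineno}: positions must be >= 1")
            out.append(rec)
    return out


def write_chimeric(records: Iterable[ChimericRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            dpos = _exonic_to_intron(r.donor_pos, r.donor_strand, "donor")
            apos = _exonic_to_intron(r.acceptor_pos, r.acceptor_strand, "acceptor")
            mate_len = r.mate_end - r.mate_start + 1
            fh.write(
                f"{r.donor_chrom}\t{dpos}\t{r.donor_strand}\t"
                f"{r.acceptor_chrom}\t{apos}\t{r.acceptor_strand}\t"
                f"1\t0\t0\t{r.read_id}\t{max(1, r.mate_start - 100)}\t100M\t"
                f"{r.mate_start}\t{mate_len}M\n"
            )


def read_evidence_files(
    sj_path: str | Path, chimeric_path: str | Path
) -> tuple[list[SpliceJunctionCount], list[ChimericRecord]]:
    return read_sj(sj_path), read_chimeric(chimeric_path)


# ---------------------------------------------------------------------------
# auxiliary annotations: SCE intervals and gene quantification


def read_sce_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Read BED intervals (0-based half-open) into per-chromosome interval
    trees holding 1-based inclusive coordinates."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}, line {lineno}: expected >= 3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start < 0 or end < start:
                raise FormatError(f"{path}, line {lineno}: bad BED interval {start}-{end}")
            if end == start:
                continue
            # [start, end) 0-based  ->  [start+1, end] 1-based inclusive
            trees.setdefault(chrom, IntervalTree()).addi(start + 1, end + 1)
    return trees


def read_gene_quant(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a gene quantification table (RSEM ``*.genes.results`` dialect:
    header with ``gene_id``, ``TPM`` and ``FPKM`` columns)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "TPM", "FPKM"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    quant: dict[str, tuple[float, float]] = {}
    for row in df.itertuples(index=False):
        tpm, fpkm = float(row.TPM), float(row.FPKM)
        if tpm < 0 or fpkm < 0:
            raise FormatError(f"{path}: negative TPM/FPKM for {row.gene_id}")
        quant[str(row.gene_id)] = (tpm, fpkm)
    return quant


def read_auxiliary(
    sce_bed_path: str | Path | None = None, quant_path: str | Path | None = None
) -> tuple[dict[str, IntervalTree] | None, dict[str, tuple[float, float]]]:
    """Read the optional SCE BED and gene quantification files.

    An absent SCE path yields ``None`` (downstream flags render as missing);
    an absent quantification path yields an empty mapping.
    """
    sce = read_sce_bed(sce_bed_path) if sce_bed_path else None
    quant = read_gene_quant(quant_path) if quant_path else {}
    return sce, quant
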