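"""Alignment-ambiguity screening of NCL events.

For each harmonized event the exonic sequence flanking the junction is
concatenated (up to 100 nt on each side, walking the spliced transcript) and
aligned externally against the reference genome and annotated transcripts
(BLAT, consumed as PSL).  An event is flagged as a likely alignment artifact
when its concatenated sequence

* has an *alternative co-linear explanation* — a single alignment crossing
  the junction midpoint with query-wide identity > 80%, e.g. through another
  isoform of the host gene — or
* *maps to multiple genomic loci* with near-equal scores (score gap < 3).

Scores follow the web-BLAT convention:
``score = matches + repMatches - misMatches - qNumInsert - tNumInsert``;
identity is ``(matches + repMatches) / qSize``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .harmonize import NCLEvent
from .io_formats import AnnotationIndex, EventKey, PSLHit, Transcript

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 100
DEFAULT_IDENTITY_THRESHOLD = 0.80
DEFAULT_SCORE_GAP = 3
DEFAULT_MIN_COVERAGE = 0.5
DEFAULT_SIDE_MARGIN = 10

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class JunctionSequence:
    """Concatenated junction-flanking sequence; the junction sits at offset
    ``donor_flank_len`` (donor-side bases first, acceptor-side bases after)."""

    key: EventKey
    sequence: str
    donor_flank_len: int
    acceptor_flank_len: int

    @property
    def midpoint(self) -> int:
        return self.donor_flank_len

    def __post_init__(self) -> None:
        if len(self.sequence) != self.donor_flank_len + self.acceptor_flank_len:
            raise ValueError("sequence length must equal the sum of the flank lengths")


@dataclass(frozen=True)
class AmbiguityCall:
    key: EventKey
    status: str  # ok | alt_colinear | multi_hit
    best_hit_score: float
    runner_up_score: float
    colinear_identity: float
    alt_flag: bool
    multi_flag: bool


# ---------------------------------------------------------------------------
# junction sequence construction


def _spliced_sequence(tx: Transcript, genome: Mapping[str, object]) -> str:
    """Spliced transcript sequence in transcript direction (5'->3')."""
    parts = [str(genome[tx.chrom][s - 1 : e]) for s, e in tx.exons]
    if tx.strand == "+":
        return "".join(parts).upper()
    return "".join(reverse_complement(p) for p in reversed(parts)).upper()


def _spliced_offset(tx: Transcript, pos: int) -> int:
    """1-based index of genomic base ``pos`` within the spliced sequence."""
    exons = tx.exons if tx.strand == "+" else list(reversed(tx.exons))
    off = 0
    for s, e in exons:
        if s <= pos <= e:
            return off + (pos - s + 1 if tx.strand == "+" else e - pos + 1)
        off += e - s + 1
    raise ValueError(f"position {pos} not exonic in transcript {tx.id}")


def build_junction_sequence(
    event: NCLEvent,
    annotation: AnnotationIndex,
    genome: Mapping[str, object],
    flank: int = DEFAULT_FLANK,
) -> JunctionSequence:
    """Concatenate the spliced exonic sequence flanking the NCL junction.

    The donor flank is the last ``<= flank`` nt of spliced transcript sequence
    ending at the donor boundary; the acceptor flank the first ``<= flank`` nt
    from the acceptor boundary.  When a single transcript carries both
    boundaries in circle orientation (acceptor upstream of donor) and the
    exonic circle is shorter than ``2*flank``, the full circle sequence is
    used, split at the junction.  Flanks walk the spliced transcript, so they
    cross co-linear exon junctions; minus-strand sequence is
    reverse-complemented by construction.
    """
    key = event.key
    donor_txs = {
        tx for _, tx in annotation.donor_owners(key.donor_chrom, key.donor_strand, key.donor_pos)
    }
    acceptor_txs = {
        tx
        for _, tx in annotation.acceptor_owners(
            key.acceptor_chrom, key.acceptor_strand, key.acceptor_pos
        )
    }
    if not donor_txs or not acceptor_txs:
        raise ValueError(f"junction of {key} is not on any annotated transcript")

    # circle orientation: one transcript owns both boundaries, acceptor first
    best_circle: tuple[int, str] | None = None  # (circle_len, tx_id)
    for tx_id in sorted(donor_txs & acceptor_txs):
        tx = annotation.transcripts[tx_id]
        d_off = _spliced_offset(tx, key.donor_pos)
        a_off = _spliced_offset(tx, key.acceptor_pos)
        if a_off <= d_off:
            circle_len = d_off - a_off + 1
            if best_circle is None or circle_len > best_circle[0]:
                best_circle = (circle_len, tx_id)

    if best_circle is not None and best_circle[0] < 2 * flank:
        circle_len, tx_id = best_circle
        tx = annotation.transcripts[tx_id]
        seq = _spliced_sequence(tx, genome)
        d_off = _spliced_offset(tx, key.donor_pos)
        a_off = _spliced_offset(tx, key.acceptor_pos)
        a_len = circle_len // 2
        d_len = circle_len - a_len
        donor_part = seq[d_off - d_len : d_off]
        acceptor_part = seq[a_off - 1 : a_off - 1 + a_len]
        return JunctionSequence(key, donor_part + acceptor_part, d_len, a_len)

    def best_flank(txs: set[str], side: str) -> str:
        best_seq, best_tx = "", None
        for tx_id in sorted(txs):
            tx = annotation.transcripts[tx_id]
            seq = _spliced_sequence(tx, genome)
            if side == "donor":
                off = _spliced_offset(tx, key.donor_pos)
                cand = seq[max(0, off - flank) : off]
            else:
                off = _spliced_offset(tx, key.acceptor_pos)
                cand = seq[off - 1 : off - 1 + flank]
            if len(cand) > len(best_seq):
                best_seq, best_tx = cand, tx_id
        return best_seq

    donor_part = best_flank(donor_txs, "donor")
    acceptor_part = best_flank(acceptor_txs, "acceptor")
    return JunctionSequence(
        key, donor_part + acceptor_part, len(donor_part), len(acceptor_part)
    )


def write_junction_fasta(
    sequences: Iterable[JunctionSequence], path: str | Path, width: int = 60
) -> None:
    """Write junction sequences as FASTA for external alignment (query id =
    event key)."""
    with open(path, "w") as fh:
        for js in sequences:
            fh.write(f">{js.key}\n")
            for i in range(0, len(js.sequence), width):
                fh.write(js.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# hit scoring and classification


def score_hit(hit: PSLHit) -> tuple[int, float]:
    """(score, identity) of one alignment, web-BLAT score convention."""
    if hit.qSize <= 0:
        raise ValueError("hit has qSize 0")
    score = hit.matches + hit.repMatches - hit.misMatches - hit.qNumInsert - hit.tNumInsert
    identity = (hit.matches + hit.repMatches) / hit.qSize
    return score, identity


def find_alt_colinear(
    hits: Sequence[PSLHit],
    junction_seq: JunctionSequence,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    side_margin: int = DEFAULT_SIDE_MARGIN,
) -> PSLHit | None:
    """A single alignment explaining the junction co-linearly, or None.

    Qualifies when it covers the junction midpoint with at least
    ``side_margin`` query bases on each side and query-wide identity strictly
    above ``identity_threshold``.
    """
    mid = junction_seq.midpoint
    best: tuple[float, PSLHit] | None = None
    for hit in hits:
        if hit.qStart > mid - side_margin or hit.qEnd < mid + side_margin:
            continue
        _, identity = score_hit(hit)
        if identity > identity_threshold:
            if best is None or identity > best[0]:
                best = (identity, hit)
    return None if best is None else best[1]


def _cluster_loci(
    hits: Sequence[PSLHit],
    self_regions: Sequence[tuple[str, int, int]] | None,
) -> list[tuple[float, bool]]:
    """Group hits into target loci; returns (locus score, is_self) per locus.

    Hits on the same target whose intervals overlap form one locus (duplicate
    alignment lines therefore collapse); a locus is *self* when it overlaps
    one of the event's own junction regions.
    """
    by_target: dict[str, list[PSLHit]] = {}
    for h in hits:
        by_target.setdefault(h.tName, []).append(h)
    loci: list[tuple[float, bool]] = []
    for tname in sorted(by_target):
        group = sorted(by_target[tname], key=lambda h: (h.tStart, h.tEnd))
        cur_start, cur_end, cur_score = None, None, 0.0
        cur_self = False

        def is_self(h: PSLHit) -> bool:
            if not self_regions:
                return False
            return any(
                chrom == h.tName and h.tStart < hi and lo <= h.tEnd
                for chrom, lo, hi in self_regions
            )

        for h in group:
            score, _ = score_hit(h)
            if cur_start is None or h.tStart >= cur_end:
                if cur_start is not None:
                    loci.append((cur_score, cur_self))
                cur_start, cur_end = h.tStart, h.tEnd
                cur_score, cur_self = score, is_self(h)
            else:
                cur_end = max(cur_end, h.tEnd)
                cur_score = max(cur_score, score)
                cur_self = cur_self or is_self(h)
        if cur_start is not None:
            loci.append((cur_score, cur_self))
    return loci


def find_multi_hit(
    hits: Sequence[PSLHit],
    score_gap: float = DEFAULT_SCORE_GAP,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    self_regions: Sequence[tuple[str, int, int]] | None = None,
) -> tuple[bool, float, float]:
    """Multi-locus ambiguity flag over genomic alignments.

    Considers hits covering at least ``min_coverage`` of the query, clustered
    into distinct target loci (the event's own donor/acceptor loci count as a
    single locus).  Returns (flag, best locus score, runner-up locus score);
    flag is True when >= 2 loci score within ``(best - score_gap, best]``.
    """
    covering = [h for h in hits if (h.qEnd - h.qStart) / h.qSize >= min_coverage]
    if not covering:
        return False, 0.0, 0.0
    loci = _cluster_loci(covering, self_regions)
    self_scores = [s for s, is_self in loci if is_self]
    other_scores = [s for s, is_self in loci if not is_self]
    scores = sorted(
        ([max(self_scores)] if self_scores else []) + other_scores, reverse=True
    )
    best = scores[0]
    runner_up = scores[1] if len(scores) > 1 else 0.0
    n_close = sum(1 for s in scores if best - score_gap < s <= best)
    return n_close >= 2, float(best), float(runner_up)


def classify_ambiguity(
    event: NCLEvent,
    hits: Sequence[PSLHit],
    junction_seq: JunctionSequence,
    genome_chroms: set[str],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    score_gap: float = DEFAULT_SCORE_GAP,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    side_margin: int = DEFAULT_SIDE_MARGIN,
) -> AmbiguityCall:
    """Classify one event as ok / alt_colinear / multi_hit.

    The alternative-co-linear screen considers genome and transcript
    alignments; the multi-hit screen considers genomic loci only.  An event
    satisfying both is reported as alt_colinear (precedence), with both flags
    retained.
    """
    key = event.key
    if not hits:
        logger.warning("junction sequence of %s aligned nowhere", key)
        return AmbiguityCall(key, "ok", 0.0, 0.0, 0.0, False, False)
    qsize = len(junction_seq.sequence)
    self_regions = [
        (key.donor_chrom, key.donor_pos - qsize, key.donor_pos + qsize),
        (key.acceptor_chrom, key.acceptor_pos - qsize, key.acceptor_pos + qsize),
    ]
    alt_hit = find_alt_colinear(hits, junction_seq, identity_threshold, side_margin)
    genome_hits = [h for h in hits if h.tName in genome_chroms]
    multi, best, runner_up = find_multi_hit(
        genome_hits, score_gap, min_coverage, self_regions
    )
    alt_identity = score_hit(alt_hit)[1] if alt_hit is not None else 0.0
    if alt_hit is not None:
        status = "alt_colinear"
    elif multi:
        status = "multi_hit"
    else:
        status = "ok"
    return AmbiguityCall(
        key, status, best, runner_up, alt_identity, alt_hit is not None, multi
    )
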