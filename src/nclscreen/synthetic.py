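"""Self-contained synthetic fixtures with planted ground truth.

Generates a random genome with non-overlapping multi-exon genes, plants NCL
events of every class (circRNA back-splices, intragenic trans-splices with
out-of-circle mate pairs, intergenic fusions), and emits everything the
screening pipeline consumes: per-detector event tables with controlled
detection probability, count dispersion and coordinate jitter; PSL alignment
fixtures realizing the intended ambiguity class of each event; splice-junction
count and chimeric read-pair tables; SCE intervals; gene quantification; and
a run configuration.  A ground-truth manifest maps every planted event to its
intended classification and counts.

The default panel mirrors a multi-detector comparison study: nine
intragenic-scope (circRNA) detectors and six intergenic-scope (gene-fusion)
detectors with detection probabilities spread over 0.3-0.9 and log-normal
multiplicative count dispersion.  Everything is driven by one seed; a fixed
seed yields a byte-identical fixture tree.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ambiguity as amb
from .io_formats import (
    ChimericRecord,
    EventKey,
    PSLHit,
    SpliceJunctionCount,
    read_annotation,
    write_chimeric,
    write_psl,
    write_sj,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ToolSpec:
    """One simulated detector."""

    name: str
    scope: str  # intragenic | intergenic
    detection_prob: float = 0.7
    dispersion: float = 0.5  # sigma of the multiplicative log-normal noise
    coordinate_base: int = 1


def default_tool_panel() -> list[ToolSpec]:
    """Nine circRNA-scope and six fusion-scope detectors."""
    circ_probs = [0.9, 0.8, 0.7, 0.6, 0.5, 0.45, 0.4, 0.35, 0.3]
    fusion_probs = [0.9, 0.7, 0.5, 0.4, 0.35, 0.3]
    panel = [
        ToolSpec(f"circdet{i + 1}", "intragenic", p, 0.5, 0 if i % 3 == 2 else 1)
        for i, p in enumerate(circ_probs)
    ]
    panel += [
        ToolSpec(f"fusdet{i + 1}", "intergenic", p, 0.5, 0 if i % 3 == 2 else 1)
        for i, p in enumerate(fusion_probs)
    ]
    return panel


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (4, 9)
    exon_length: tuple[int, int] = (120, 260)
    intron_length: tuple[int, int] = (100, 400)
    intergenic_gap: tuple[int, int] = (300, 800)
    n_circ: int = 24
    n_trans: int = 8
    n_fusion: int = 12
    n_alt_colinear: int = 6
    n_multi_hit: int = 6
    tools: list[ToolSpec] = field(default_factory=default_tool_panel)
    jitter_fraction: float = 0.3
    max_jitter: int = 5
    flank: int = 100
    alt_identity: float = 0.85
    multi_hit_mismatches: int = 1  # score gap of the planted second locus = 2x this
    n_ncl_log_mean: float = 1.6
    n_ncl_log_sd: float = 1.0
    sj_count_range: tuple[int, int] = (5, 80)
    total_raw_reads: int = 20_000_000
    total_mapped_reads: int = 15_000_000

    def __post_init__(self) -> None:
        if min(self.n_circ, self.n_trans, self.n_fusion,
               self.n_alt_colinear, self.n_multi_hit) < 0:
            raise ValueError("event counts must be >= 0")
        for t in self.tools:
            if not 0.0 <= t.detection_prob <= 1.0:
                raise ValueError(f"tool {t.name}: detection_prob outside [0,1]")
        if (self.n_alt_colinear or self.n_multi_hit) and self.exon_length[0] < self.flank:
            raise ValueError(
                "planted ambiguous events need exons at least one flank long"
            )


@dataclass
class SimTranscript:
    id: str
    exons: list[tuple[int, int]]  # genomic ascending, 1-based inclusive


@dataclass
class SimGene:
    id: str
    name: str
    chrom: str
    strand: str
    transcripts: list[SimTranscript]


@dataclass
class Reference:
    chrom_seqs: dict[str, bytearray]
    genes: list[SimGene]
    homolog_slots: list[tuple[str, int, int, str, str]]  # chrom, start, end, gene, tx
    dup_slots: list[tuple[str, int, int]]

    def chrom_strings(self) -> dict[str, str]:
        return {c: s.decode() for c, s in self.chrom_seqs.items()}

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.chrom_seqs):
                fh.write(f">{chrom}\n")
                seq = self.chrom_seqs[chrom].decode()
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gtf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene in self.genes:
                for tx in gene.transcripts:
                    for s, e in tx.exons:
                        attrs = (
                            f'gene_id "{gene.id}"; transcript_id "{tx.id}"; '
                            f'gene_name "{gene.name}";'
                        )
                        fh.write(
                            f"{gene.chrom}\tsim\texon\t{s}\t{e}\t.\t"
                            f"{gene.strand}\t.\t{attrs}\n"
                        )


@dataclass
class PlantedEvent:
    """One planted NCL event and everything the pipeline should recover."""

    key: EventKey
    cls: str  # circ | trans | fusion
    status: str  # ok | alt_colinear | multi_hit
    donor_gene: str
    acceptor_gene: str
    donor_tx: str
    acceptor_tx: str
    homolog_tx: str | None = None
    dup_slot: tuple[str, int, int] | None = None
    per_tool: dict[str, int] = field(default_factory=dict)
    n_d: int = 0
    n_a: int = 0
    out_of_circle: int = 0
    sce_donor: bool = False
    sce_acceptor: bool = False

    @property
    def locus_class(self) -> str:
        return "intragenic" if self.cls in ("circ", "trans") else "intergenic"


@dataclass
class GroundTruth:
    config: SimConfig
    events: list[PlantedEvent]

    def by_key(self) -> dict[EventKey, PlantedEvent]:
        return {ev.key: ev for ev in self.events}

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        payload = {
            "seed": self.config.seed,
            "events": [
                {
                    "key": str(ev.key),
                    "class": ev.cls,
                    "status": ev.status,
                    "locus_class": ev.locus_class,
                    "donor_gene": ev.donor_gene,
                    "acceptor_gene": ev.acceptor_gene,
                    "per_tool": ev.per_tool,
                    "n_d": ev.n_d,
                    "n_a": ev.n_a,
                    "out_of_circle": ev.out_of_circle,
                    "sce_donor": ev.sce_donor,
                    "sce_acceptor": ev.sce_acceptor,
                }
                for ev in self.events
            ],
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=1) + "\n")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("key\tclass\tstatus\tlocus_class\tdonor_gene\tacceptor_gene\t"
                     "n_d\tn_a\tout_of_circle\n")
            for ev in self.events:
                fh.write(
                    f"{ev.key}\t{ev.cls}\t{ev.status}\t{ev.locus_class}\t"
                    f"{ev.donor_gene}\t{ev.acceptor_gene}\t{ev.n_d}\t{ev.n_a}\t"
                    f"{ev.out_of_circle}\n"
                )


# ---------------------------------------------------------------------------
# reference simulation


def simulate_reference(config: SimConfig, rng: np.random.Generator) -> Reference:
    """Random genome and annotation skeleton.

    Homolog slots (one single-exon gene per planted alternative-co-linear
    event, later overwritten with a mutated junction sequence) and
    duplication slots (intergenic copies of a donor flank, for multi-hit
    events) are reserved here and filled after events are planted.
    """
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    cursors = {c: 0 for c in chroms}
    genes: list[SimGene] = []
    homolog_slots: list[tuple[str, int, int, str, str]] = []
    dup_slots: list[tuple[str, int, int]] = []

    def gap(chrom: str) -> None:
        cursors[chrom] += int(rng.integers(*config.intergenic_gap, endpoint=True))

    for gi in range(config.n_genes):
        chrom = chroms[gi % len(chroms)]
        gap(chrom)
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(*config.exons_per_gene, endpoint=True))
        exons: list[tuple[int, int]] = []
        pos = cursors[chrom] + 1
        for ei in range(n_ex):
            length = int(rng.integers(*config.exon_length, endpoint=True))
            exons.append((pos, pos + length - 1))
            pos += length
            if ei < n_ex - 1:
                pos += int(rng.integers(*config.intron_length, endpoint=True))
        cursors[chrom] = exons[-1][1]
        gid = f"G{gi + 1:03d}"
        genes.append(
            SimGene(gid, f"gene{gi + 1}", chrom, strand,
                    [SimTranscript(f"{gid}.t1", exons)])
        )
    for hi in range(config.n_alt_colinear):
        chrom = chroms[hi % len(chroms)]
        gap(chrom)
        start = cursors[chrom] + 1
        end = start + 2 * config.flank - 1
        cursors[chrom] = end
        gid = f"H{hi + 1:03d}"
        genes.append(
            SimGene(gid, f"homolog{hi + 1}", chrom, "+",
                    [SimTranscript(f"{gid}.t1", [(start, end)])])
        )
        homolog_slots.append((chrom, start, end, gid, f"{gid}.t1"))
    for di in range(config.n_multi_hit):
        chrom = chroms[di % len(chroms)]
        gap(chrom)
        start = cursors[chrom] + 1
        end = start + config.flank - 1
        cursors[chrom] = end
        dup_slots.append((chrom, start, end))

    chrom_seqs: dict[str, bytearray] = {}
    for chrom in chroms:
        length = cursors[chrom] + 1000  # tail room for out-of-circle mates
        arr = _BASES[rng.integers(0, 4, size=length)]
        chrom_seqs[chrom] = bytearray(arr.tobytes())
    return Reference(chrom_seqs, genes, homolog_slots, dup_slots)


# ---------------------------------------------------------------------------
# event planting


def _td_exons(gene: SimGene) -> list[tuple[int, int]]:
    """Exons in transcript direction (5'->3')."""
    exons = gene.transcripts[0].exons
    return exons if gene.strand == "+" else list(reversed(exons))


def _donor_pos(gene: SimGene, td_index: int) -> int:
    s, e = _td_exons(gene)[td_index]
    return e if gene.strand == "+" else s


def _acceptor_pos(gene: SimGene, td_index: int) -> int:
    s, e = _td_exons(gene)[td_index]
    return s if gene.strand == "+" else e


def plant_events(config: SimConfig, reference: Reference, rng: np.random.Generator) -> list[PlantedEvent]:
    """Plant circRNA, trans-spliced and fusion events at annotated boundaries.

    Circular and trans-spliced events place the donor downstream of the
    acceptor (in transcript direction) within one gene; planted ambiguous
    events are appended as extra circ / fusion events linked to a homolog or
    duplication slot.
    """
    normal = [g for g in reference.genes if len(g.transcripts[0].exons) >= 2]
    if not normal:
        raise ValueError("no multi-exon genes to plant events in")
    used: set[EventKey] = set()
    events: list[PlantedEvent] = []

    def plant_intragenic(cls: str, status: str) -> PlantedEvent:
        for _ in range(1000):
            gene = normal[int(rng.integers(len(normal)))]
            n_ex = len(gene.transcripts[0].exons)
            i = int(rng.integers(0, n_ex - 1))            # acceptor exon (td order)
            j = int(rng.integers(i + 1, n_ex))            # donor exon strictly after
            key = EventKey(
                gene.chrom, _donor_pos(gene, j), gene.strand,
                gene.chrom, _acceptor_pos(gene, i), gene.strand,
            )
            if key in used:
                continue
            used.add(key)
            tx = gene.transcripts[0].id
            return PlantedEvent(key, cls, status, gene.id, gene.id, tx, tx)
        raise ValueError("could not plant a unique intragenic event; too few exons")

    def plant_fusion(status: str) -> PlantedEvent:
        for _ in range(1000):
            g1, g2 = (
                normal[int(rng.integers(len(normal)))],
                normal[int(rng.integers(len(normal)))],
            )
            if g1.id == g2.id:
                continue
            j = int(rng.integers(len(g1.transcripts[0].exons)))
            i = int(rng.integers(len(g2.transcripts[0].exons)))
            key = EventKey(
                g1.chrom, _donor_pos(g1, j), g1.strand,
                g2.chrom, _acceptor_pos(g2, i), g2.strand,
            )
            if key in used:
                continue
            used.add(key)
            return PlantedEvent(
                key, "fusion", status, g1.id, g2.id,
                g1.transcripts[0].id, g2.transcripts[0].id,
            )
        raise ValueError("could not plant a unique fusion event")

    for _ in range(config.n_circ):
        events.append(plant_intragenic("circ", "ok"))
    for _ in range(config.n_trans):
        events.append(plant_intragenic("trans", "ok"))
    for _ in range(config.n_fusion):
        events.append(plant_fusion("ok"))
    for k in range(config.n_alt_colinear):
        ev = plant_intragenic("circ", "alt_colinear") if k % 2 == 0 else plant_fusion("alt_colinear")
        ev.homolog_tx = reference.homolog_slots[k][4]
        events.append(ev)
    for k in range(config.n_multi_hit):
        ev = plant_intragenic("circ", "multi_hit") if k % 2 == 0 else plant_fusion("multi_hit")
        ev.dup_slot = reference.dup_slots[k]
        events.append(ev)
    return events


# ---------------------------------------------------------------------------
# detector tables


def _scope_of(ev: PlantedEvent) -> str:
    return "intragenic" if ev.cls in ("circ", "trans") else "intergenic"


def emit_tool_reports(
    events: list[PlantedEvent],
    config: SimConfig,
    rng: np.random.Generator,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write one event table per tool; fills ``per_tool`` of each event.

    Each in-scope tool detects an event with its detection probability (at
    least one tool always does); the reported count is the event's true count
    under multiplicative log-normal dispersion, floored at 1; a configurable
    fraction of reports carries <= ``max_jitter`` bp coordinate jitter to
    exercise boundary snapping.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows_by_tool: dict[str, list[tuple]] = {t.name: [] for t in config.tools}
    for ev in events:
        scope = _scope_of(ev)
        in_scope = [t for t in config.tools if t.scope == scope]
        true_count = max(1, round(float(rng.lognormal(config.n_ncl_log_mean, config.n_ncl_log_sd))))
        detected = [t for t in in_scope if rng.random() < t.detection_prob]
        if not detected and in_scope:
            detected = [max(in_scope, key=lambda t: t.detection_prob)]
        for tool in detected:
            noise = float(rng.lognormal(0.0, tool.dispersion)) if tool.dispersion > 0 else 1.0
            reported = max(1, round(true_count * noise))
            dpos, apos = ev.key.donor_pos, ev.key.acceptor_pos
            if config.jitter_fraction > 0 and rng.random() < config.jitter_fraction:
                dpos += int(rng.integers(-config.max_jitter, config.max_jitter, endpoint=True))
                apos += int(rng.integers(-config.max_jitter, config.max_jitter, endpoint=True))
            ev.per_tool[tool.name] = reported
            rows_by_tool[tool.name].append(
                (ev.key.donor_chrom, dpos, ev.key.donor_strand,
                 ev.key.acceptor_chrom, apos, ev.key.acceptor_strand, reported)
            )
    paths: dict[str, Path] = {}
    for tool in config.tools:
        path = outdir / f"{tool.name}.tsv"
        with open(path, "w") as fh:
            fh.write("donor_chrom\tdonor_pos\tdonor_strand\t"
                     "acceptor_chrom\tacceptor_pos\tacceptor_strand\tn_ncl\n")
            for dc, dp, ds, ac, ap, as_, n in rows_by_tool[tool.name]:
                if tool.coordinate_base == 0:
                    ap -= 1  # acceptor written as 0-based start-like
                fh.write(f"{dc}\t{dp}\t{ds}\t{ac}\t{ap}\t{as_}\t{n}\n")
        paths[tool.name] = path
    return paths


# ---------------------------------------------------------------------------
# alignment fixtures


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    """Substitute ``n_mut`` distinct positions with a different base."""
    if n_mut <= 0:
        return seq
    chars = list(seq)
    positions = rng.choice(len(chars), size=min(n_mut, len(chars)), replace=False)
    for p in sorted(int(x) for x in positions):
        others = [b for b in "ACGT" if b != chars[p]]
        chars[p] = others[int(rng.integers(3))]
    return "".join(chars)


def _self_hits(ev: PlantedEvent, js: amb.JunctionSequence, chrom_len: dict[str, int]) -> list[PSLHit]:
    key, d, a = ev.key, js.donor_flank_len, js.acceptor_flank_len
    qsize = d + a

    def hit(qs: int, qe: int, tname: str, ts: int, te: int, strand: str) -> PSLHit:
        return PSLHit(
            matches=qe - qs, misMatches=0, repMatches=0, nCount=0,
            qNumInsert=0, qBaseInsert=0, tNumInsert=0, tBaseInsert=0,
            strand=strand, qName=str(key), qSize=qsize, qStart=qs, qEnd=qe,
            tName=tname, tSize=chrom_len[tname], tStart=ts, tEnd=te,
            blockCount=1, blockSizes=(qe - qs,), qStarts=(qs,), tStarts=(ts,),
        )

    if key.donor_strand == "+":
        donor = hit(0, d, key.donor_chrom, key.donor_pos - d, key.donor_pos, "+")
    else:
        donor = hit(0, d, key.donor_chrom, key.donor_pos - 1, key.donor_pos - 1 + d, "-")
    if key.acceptor_strand == "+":
        acceptor = hit(d, qsize, key.acceptor_chrom, key.acceptor_pos - 1,
                       key.acceptor_pos - 1 + a, "+")
    else:
        acceptor = hit(d, qsize, key.acceptor_chrom, key.acceptor_pos - a,
                       key.acceptor_pos, "-")
    return [donor, acceptor]


def emit_alignment_fixtures(
    events: list[PlantedEvent],
    sequences: dict[EventKey, amb.JunctionSequence],
    reference: Reference,
    config: SimConfig,
    rng: np.random.Generator,
    outdir: str | Path,
) -> None:
    """Write genome.psl / transcripts.psl and apply the genome overwrites.

    Every event gets its pair of self-locus hits; multi-hit events an extra
    genomic hit at the duplication slot scoring within ``2*multi_hit_mismatches``
    of the best; alternative-co-linear events a transcript hit crossing the
    junction midpoint at the planted identity.  The homolog exon and the
    duplication slots are overwritten in the genome with the correspondingly
    mutated junction sequence so the fixtures stay sequence-consistent.
    """
    outdir = Path(outdir)
    chrom_len = {c: len(s) for c, s in reference.chrom_seqs.items()}
    genome_hits: list[PSLHit] = []
    tx_hits: list[PSLHit] = []
    for ev in events:
        js = sequences[ev.key]
        qsize = len(js.sequence)
        genome_hits.extend(_self_hits(ev, js, chrom_len))
        if ev.status == "multi_hit":
            chrom, start, end = ev.dup_slot  # type: ignore[misc]
            length = end - start + 1
            mm = config.multi_hit_mismatches
            copy = _mutate(js.sequence[:length], mm, rng)
            reference.chrom_seqs[chrom][start - 1 : end] = copy.encode()
            genome_hits.append(
                PSLHit(
                    matches=length - mm, misMatches=mm, repMatches=0, nCount=0,
                    qNumInsert=0, qBaseInsert=0, tNumInsert=0, tBaseInsert=0,
                    strand="+", qName=str(ev.key), qSize=qsize,
                    qStart=0, qEnd=length, tName=chrom, tSize=chrom_len[chrom],
                    tStart=start - 1, tEnd=end, blockCount=1,
                    blockSizes=(length,), qStarts=(0,), tStarts=(start - 1,),
                )
            )
        elif ev.status == "alt_colinear":
            slot = next(s for s in reference.homolog_slots if s[4] == ev.homolog_tx)
            chrom, start, end, _gid, tx_id = slot
            n_mut = round((1.0 - config.alt_identity) * qsize)
            homolog = _mutate(js.sequence, n_mut, rng)
            reference.chrom_seqs[chrom][start - 1 : start - 1 + qsize] = homolog.encode()
            tx_hits.append(
                PSLHit(
                    matches=qsize - n_mut, misMatches=n_mut, repMatches=0, nCount=0,
                    qNumInsert=0, qBaseInsert=0, tNumInsert=0, tBaseInsert=0,
                    strand="+", qName=str(ev.key), qSize=qsize,
                    qStart=0, qEnd=qsize, tName=tx_id, tSize=qsize,
                    tStart=0, tEnd=qsize, blockCount=1,
                    blockSizes=(qsize,), qStarts=(0,), tStarts=(0,),
                )
            )
    write_psl(genome_hits, outdir / "genome.psl")
    write_psl(tx_hits, outdir / "transcripts.psl")


# ---------------------------------------------------------------------------
# evidence fixtures


def _adjacent_intron(gene: SimGene, td_index: int, side: str) -> tuple[int, int] | None:
    """The annotated intron leaving (donor) / entering (acceptor) the boundary
    of td-order exon ``td_index``, or None at a transcript end."""
    exons = gene.transcripts[0].exons
    n = len(exons)
    g = td_index if gene.strand == "+" else n - 1 - td_index
    if side == "donor":
        nxt = g + 1 if gene.strand == "+" else g - 1
    else:
        nxt = g - 1 if gene.strand == "+" else g + 1
    if not 0 <= nxt < n:
        return None
    lo, hi = (g, nxt) if g < nxt else (nxt, g)
    return exons[lo][1] + 1, exons[hi][0] - 1


def _event_td_indexes(ev: PlantedEvent, reference: Reference) -> tuple[SimGene, int, SimGene, int]:
    by_id = {g.id: g for g in reference.genes}
    dg, ag = by_id[ev.donor_gene], by_id[ev.acceptor_gene]
    d_idx = next(
        i for i in range(len(dg.transcripts[0].exons))
        if _donor_pos(dg, i) == ev.key.donor_pos
    )
    a_idx = next(
        i for i in range(len(ag.transcripts[0].exons))
        if _acceptor_pos(ag, i) == ev.key.acceptor_pos
    )
    return dg, d_idx, ag, a_idx


def emit_evidence_fixtures(
    events: list[PlantedEvent],
    reference: Reference,
    config: SimConfig,
    rng: np.random.Generator,
    outdir: str | Path,
) -> None:
    """Write the SJ count table, chimeric records, SCE BED and quantification.

    Every annotated intron receives a background unique-read count; the
    planted N_D / N_A of each event are then the counts of the introns
    adjacent to its boundaries (recorded in the manifest).  Trans-spliced
    events get chimeric read pairs whose mates fall outside the circle;
    circRNA events get mates inside it.
    """
    outdir = Path(outdir)
    lo, hi = config.sj_count_range
    sj_records: list[SpliceJunctionCount] = []
    sj_map: dict[tuple[str, int, int], int] = {}
    for gene in reference.genes:
        exons = gene.transcripts[0].exons
        for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
            intron = (gene.chrom, e1 + 1, s2 - 1)
            count = int(rng.integers(lo, hi, endpoint=True))
            sj_map[intron] = count
            sj_records.append(
                SpliceJunctionCount(gene.chrom, intron[1], intron[2], gene.strand, count)
            )
    sj_records.sort(key=lambda r: (r.chrom, r.intron_start, r.intron_end))
    write_sj(sj_records, outdir / "sj.tab")

    chimeric: list[ChimericRecord] = []
    read_no = 0
    for ev in events:
        dg, d_idx, ag, a_idx = _event_td_indexes(ev, reference)
        d_intron = _adjacent_intron(dg, d_idx, "donor")
        a_intron = _adjacent_intron(ag, a_idx, "acceptor")
        ev.n_d = sj_map.get((dg.chrom,) + d_intron, 0) if d_intron else 0
        ev.n_a = sj_map.get((ag.chrom,) + a_intron, 0) if a_intron else 0
        if ev.locus_class != "intragenic":
            continue
        key = ev.key
        circle_lo = min(key.donor_pos, key.acceptor_pos)
        circle_hi = max(key.donor_pos, key.acceptor_pos)

        def add_pair(mate_start: int, mate_len: int = 50) -> None:
            nonlocal read_no
            read_no += 1
            chimeric.append(
                ChimericRecord(
                    key.donor_chrom, key.donor_pos, key.donor_strand,
                    key.acceptor_chrom, key.acceptor_pos, key.acceptor_strand,
                    f"read{read_no:05d}", key.donor_chrom,
                    mate_start, mate_start + mate_len - 1,
                )
            )

        if circle_hi - circle_lo >= 60:  # inside mates for every circle big enough
            add_pair(circle_lo + 5)
            add_pair(circle_lo + 12)
        if ev.cls == "trans":
            ev.out_of_circle = int(rng.integers(2, 6, endpoint=True))
            for t in range(ev.out_of_circle):
                add_pair(circle_hi + 100 + 60 * t)
    write_chimeric(chimeric, outdir / "chimeric.junction")

    # SCE intervals over the first two intragenic junctions
    sce_intervals: list[tuple[str, int, int]] = []
    for ev in [e for e in events if e.locus_class == "intragenic"][:2]:
        sce_intervals.append(
            (ev.key.donor_chrom, ev.key.donor_pos - 20, ev.key.donor_pos + 20)
        )
    with open(outdir / "sce.bed", "w") as fh:
        for chrom, start, end in sorted(sce_intervals):
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")  # 1-based inclusive -> BED
    for ev in events:
        ev.sce_donor = any(
            c == ev.key.donor_chrom and s <= ev.key.donor_pos <= e
            for c, s, e in sce_intervals
        )
        ev.sce_acceptor = any(
            c == ev.key.acceptor_chrom and s <= ev.key.acceptor_pos <= e
            for c, s, e in sce_intervals
        )

    with open(outdir / "quant.genes.results", "w") as fh:
        fh.write("gene_id\ttranscript_id(s)\tlength\teffective_length\t"
                 "expected_count\tTPM\tFPKM\n")
        for gene in reference.genes:
            tpm = round(float(rng.uniform(0.5, 200.0)), 2)
            fpkm = round(tpm * float(rng.uniform(0.5, 1.5)), 2)
            length = sum(e - s + 1 for s, e in gene.transcripts[0].exons)
            fh.write(
                f"{gene.id}\t{gene.transcripts[0].id}\t{length}\t{length}\t"
                f"100.00\t{tpm}\t{fpkm}\n"
            )


# ---------------------------------------------------------------------------
# orchestration


def _write_run_config(config: SimConfig, outdir: Path) -> None:
    tools = []
    for t in config.tools:
        tools.append(
            {
                "name": t.name,
                "path": f"tools/{t.name}.tsv",
                "scope": t.scope,
                "coordinate_base": t.coordinate_base,
                "has_header": True,
                "columns": {
                    "donor_chrom": 0, "donor_pos": 1, "donor_strand": 2,
                    "acceptor_chrom": 3, "acceptor_pos": 4, "acceptor_strand": 5,
                    "n_ncl": 6,
                },
            }
        )
    payload = {
        "genome": "genome.fa",
        "annotation": "annotation.gtf",
        "psl": ["genome.psl", "transcripts.psl"],
        "sj": "sj.tab",
        "chimeric": "chimeric.junction",
        "sce": "sce.bed",
        "quant": "quant.genes.results",
        "library": {
            "total_raw_reads": config.total_raw_reads,
            "total_mapped_reads": config.total_mapped_reads,
        },
        "tools": tools,
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(payload, sort_keys=False))


def simulate(config: SimConfig, outdir: str | Path) -> GroundTruth:
    """Generate a full fixture tree under ``outdir`` and return its manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    reference = simulate_reference(config, rng)
    events = plant_events(config, reference, rng)
    reference.write_gtf(outdir / "annotation.gtf")
    annotation = read_annotation(outdir / "annotation.gtf")
    genome_view = reference.chrom_strings()

    sequences: dict[EventKey, amb.JunctionSequence] = {}
    for ev in events:
        shim = _EventShim(ev)
        sequences[ev.key] = amb.build_junction_sequence(
            shim, annotation, genome_view, config.flank
        )

    emit_alignment_fixtures(events, sequences, reference, config, rng, outdir)
    reference.write_fasta(outdir / "genome.fa")  # after overwrites
    amb.write_junction_fasta(
        [sequences[ev.key] for ev in events], outdir / "junctions.fa"
    )
    emit_tool_reports(events, config, rng, outdir / "tools")
    emit_evidence_fixtures(events, reference, config, rng, outdir)
    _write_run_config(config, outdir)
    truth = GroundTruth(config, events)
    truth.save(outdir)
    return truth


class _EventShim:
    """Adapter giving a PlantedEvent the interface junction-sequence building
    expects (key + gene sets)."""

    def __init__(self, ev: PlantedEvent) -> None:
        self.key = ev.key
        self.donor_genes = frozenset({ev.donor_gene})
        self.acceptor_genes = frozenset({ev.acceptor_gene})


def noiseless(config: SimConfig | None = None, **overrides) -> SimConfig:
    """A copy of ``config`` with every stochastic distortion switched off:
    all tools detect every in-scope event, report the true count, and apply
    no coordinate jitter."""
    base = config or SimConfig()
    cfg = dataclasses.replace(base, jitter_fraction=0.0, **overrides)
    cfg.tools = [
        dataclasses.replace(t, detection_prob=1.0, dispersion=0.0) for t in base.tools
    ]
    return cfg
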