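"""End-to-end orchestration: configuration loading and the full screening run.

A run configuration (YAML or JSON) names the detector tables (with their
column dialects), the reference genome and annotation, the PSL alignment
files of the junction-flanking sequences, the splice-junction and chimeric
read tables, optional SCE/quantification annotations, and the library sizes.
``run()`` harmonizes, screens, scores and writes the result tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pyfaidx
import yaml

from . import ambiguity as amb
from . import evidence as evid
from . import harmonize as harm
from . import io_formats as io
from . import metrics as met
from . import report as rep

logger = logging.getLogger(__name__)


@dataclass
class RunParams:
    snap_dist: int = harm.DEFAULT_SNAP_DIST
    flank: int = amb.DEFAULT_FLANK
    identity_threshold: float = amb.DEFAULT_IDENTITY_THRESHOLD
    score_gap: float = amb.DEFAULT_SCORE_GAP
    min_coverage: float = amb.DEFAULT_MIN_COVERAGE
    side_margin: int = amb.DEFAULT_SIDE_MARGIN
    kappa: float = met.DEFAULT_KAPPA


@dataclass
class RunConfig:
    genome: Path
    annotation: Path
    tools: list[io.ToolConfig]
    psl: list[Path] = field(default_factory=list)
    sj: Path | None = None
    chimeric: Path | None = None
    sce: Path | None = None
    quant: Path | None = None
    total_raw_reads: int = 1_000_000
    total_mapped_reads: int = 1_000_000
    params: RunParams = field(default_factory=RunParams)

    def tools_for_class(self, locus_class: str) -> list[str]:
        return [
            t.tool_name for t in self.tools if t.scope in (locus_class, "both")
        ]


def load_config(path: str | Path, overrides: Mapping[str, object] | None = None) -> RunConfig:
    """Load a run configuration; relative paths resolve against the file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def resolve(p: str | None) -> Path | None:
        return None if p is None else (base / p)

    tools = []
    for block in raw["tools"]:
        tools.append(
            io.ToolConfig(
                tool_name=block["name"],
                path=base / block["path"],
                column_map=block["columns"],
                coordinate_base=int(block.get("coordinate_base", 1)),
                has_header=bool(block.get("has_header", False)),
                scope=block.get("scope", "both"),
                zero_based_kind=block.get(
                    "zero_based_kind",
                    {"donor_pos": "end_like", "acceptor_pos": "start_like"},
                ),
            )
        )
    library = raw.get("library", {})
    params = RunParams(**raw.get("params", {}))
    if overrides:
        for k, v in overrides.items():
            setattr(params, k, v)
    return RunConfig(
        genome=base / raw["genome"],
        annotation=base / raw["annotation"],
        tools=tools,
        psl=[base / p for p in raw.get("psl", [])],
        sj=resolve(raw.get("sj")),
        chimeric=resolve(raw.get("chimeric")),
        sce=resolve(raw.get("sce")),
        quant=resolve(raw.get("quant")),
        total_raw_reads=int(library.get("total_raw_reads", 1_000_000)),
        total_mapped_reads=int(library.get("total_mapped_reads", 1_000_000)),
        params=params,
    )


@dataclass
class RunResult:
    events: list[harm.NCLEvent]
    rejections: list[harm.Rejection]
    sequences: dict[io.EventKey, amb.JunctionSequence]
    calls: dict[io.EventKey, amb.AmbiguityCall]
    evidence: dict[io.EventKey, evid.JunctionEvidence]
    metrics: dict[io.EventKey, met.MetricsRow]
    results: dict[str, object]  # "intragenic"/"intergenic"/"ambiguous" frames
    coverage: rep.CoverageMatrix | None
    accounting: dict[str, dict[str, int]]


def harmonize_all(
    config: RunConfig, annotation: io.AnnotationIndex
) -> tuple[list[harm.NCLEvent], list[harm.Rejection]]:
    per_tool: dict[str, list[harm.HarmonizedRecord]] = {}
    rejections: list[harm.Rejection] = []
    for tool in config.tools:
        records = io.read_tool_events(tool)
        kept, rejected = harm.harmonize_tool_report(
            tool.tool_name, records, annotation, config.params.snap_dist
        )
        per_tool[tool.tool_name] = kept
        rejections.extend(rejected)
    return harm.merge_tool_reports(per_tool), rejections


def build_sequences(
    events: Sequence[harm.NCLEvent],
    annotation: io.AnnotationIndex,
    genome: Mapping[str, object],
    flank: int,
) -> dict[io.EventKey, amb.JunctionSequence]:
    return {
        ev.key: amb.build_junction_sequence(ev, annotation, genome, flank)
        for ev in events
    }


def classify_all(
    events: Sequence[harm.NCLEvent],
    sequences: Mapping[io.EventKey, amb.JunctionSequence],
    psl_paths: Sequence[Path],
    genome_chroms: set[str],
    params: RunParams,
) -> dict[io.EventKey, amb.AmbiguityCall]:
    hits_by_query: dict[str, list[io.PSLHit]] = {}
    for path in psl_paths:
        for hit in io.read_psl(path):
            hits_by_query.setdefault(hit.qName, []).append(hit)
    calls = {}
    for ev in events:
        calls[ev.key] = amb.classify_ambiguity(
            ev,
            hits_by_query.get(str(ev.key), []),
            sequences[ev.key],
            genome_chroms,
            identity_threshold=params.identity_threshold,
            score_gap=params.score_gap,
            min_coverage=params.min_coverage,
            side_margin=params.side_margin,
        )
    return calls


def run(
    config: RunConfig,
    outdir: str | Path | None = None,
    mode: str = "drop_ambiguous",
    make_plots: bool = False,
) -> RunResult:
    """Execute the full post-screening pipeline.

    When ``outdir`` is given the union tables, audit table, coverage matrix,
    supporting-tool histogram and cumulative-distribution tables are written
    there (byte-deterministic for identical inputs).
    """
    annotation = io.read_annotation(config.annotation)
    genome = pyfaidx.Fasta(str(config.genome))
    genome_chroms = set(genome.keys())

    events, rejections = harmonize_all(config, annotation)
    sequences = build_sequences(events, annotation, genome, config.params.flank)
    calls = classify_all(
        events, sequences, config.psl, genome_chroms, config.params
    )

    sj_records = io.read_sj(config.sj) if config.sj else []
    chimeric = io.read_chimeric(config.chimeric) if config.chimeric else []
    sj_index = evid.build_sj_index(sj_records)
    evidence = {
        ev.key: evid.collect_evidence(ev, sj_index, annotation, chimeric)
        for ev in events
    }

    sce_trees, quant = io.read_auxiliary(config.sce, config.quant)
    metrics = {}
    for ev in events:
        metrics[ev.key] = met.build_metrics_row(
            ev,
            config.tools_for_class(ev.locus_class),
            evidence[ev.key],
            quant,
            sce_trees,
            config.total_raw_reads,
            config.total_mapped_reads,
            kappa=config.params.kappa,
        )

    tool_order = [t.tool_name for t in config.tools]
    results = rep.assemble_results(events, calls, evidence, metrics, tool_order, mode)
    coverage = rep.coverage_summary(events, calls, tool_order) if events else None
    accounting = {}
    for cls in ("intragenic", "intergenic"):
        in_class = [ev for ev in events if ev.locus_class == cls]
        amb_calls = [calls[ev.key] for ev in in_class]
        accounting[cls] = {
            "before": len(in_class),
            "alt_colinear": sum(1 for c in amb_calls if c.status == "alt_colinear"),
            "multi_hit": sum(1 for c in amb_calls if c.status == "multi_hit"),
            "after": sum(1 for c in amb_calls if c.status == "ok"),
        }

    if outdir is not None:
        outdir = Path(outdir)
        cdfs = rep.export_distributions(results)
        rep.write_outputs(outdir, results, coverage, cdfs, rejections)
        amb.write_junction_fasta(
            [sequences[ev.key] for ev in events], outdir / "junctions.fa"
        )
        if make_plots and coverage is not None:
            rep.plot_summaries(outdir, coverage)
    return RunResult(
        events, rejections, sequences, calls, evidence, metrics,
        results, coverage, accounting,
    )
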