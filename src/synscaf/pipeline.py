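"""End-to-end orchestration: maps -> chimera split -> scaffold -> stats.

Stage order follows the scaffolding recipe: best-hit selection, spurious-run
filtering, synteny anchors, marker anchors, chimera detection and splitting,
both maps rebuilt on the split contigs, assignment/ordering/orientation,
then sequence + AGP emission.  Every stage's intermediate is written to the
output directory and a run manifest records parameters and counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import anchor_maps, chimera, formats_io, scaffolder
from .anchor_maps import AnchorPoint, FilterParams, MarkerRecord
from .chimera import Breakpoint, ChunkParams
from .formats_io import GeneModel, ScaffoldLayout, SeqRecord, TabularHit

__all__ = ["PipelineConfig", "PipelineResult", "run_scaffold_pipeline", "run_scaffold_files"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    contigs: str = ""
    gene_models: str = ""
    hits: str = ""
    marker_map: str = ""
    flank_hits: str = ""
    out_dir: str = "."
    filter_params: FilterParams = field(default_factory=FilterParams)
    chunk_params: ChunkParams = field(default_factory=ChunkParams)
    weights: dict[str, float] = field(default_factory=lambda: dict(scaffolder.DEFAULT_WEIGHTS))
    within_gap: int = 100
    unplaced_gap: int = 1000
    min_marker_identity: float = 95.0
    log_level: str = "INFO"


@dataclass
class PipelineResult:
    layout: ScaffoldLayout
    breakpoints: list[Breakpoint]
    anchors: list[AnchorPoint]
    contigs: list[SeqRecord]
    name_map: dict[str, list[tuple[str, int, int]]]
    records: list[SeqRecord]
    agp_rows: list
    stats: scaffolder.PlacementStats
    counts: dict[str, int]
    marker_report: dict[str, int]


def run_scaffold_pipeline(
    contigs: Sequence[SeqRecord],
    genes: Sequence[GeneModel],
    hits: Sequence[TabularHit],
    markers: Sequence[MarkerRecord] = (),
    flank_hits: Sequence[TabularHit] = (),
    filter_params: FilterParams = FilterParams(),
    chunk_params: ChunkParams = ChunkParams(),
    weights: Mapping[str, float] | None = None,
    within_gap: int = 100,
    unplaced_gap: int = 1000,
    min_marker_identity: float = 95.0,
) -> PipelineResult:
    """Run the full scaffolding pipeline in memory."""
    weights = dict(weights or scaffolder.DEFAULT_WEIGHTS)
    counts: dict[str, int] = {"hits_in": len(hits), "contigs_in": len(contigs)}

    chromosome_of = {g.isoform_id: g.chromosome for g in genes}
    best = anchor_maps.select_best_hits(hits)
    counts["best_hits"] = len(best)
    filtered = anchor_maps.filter_spurious_runs(
        best.values(), chromosome_of, filter_params
    )
    counts["hits_after_filter"] = len(filtered)
    synteny_anchors = anchor_maps.build_synteny_anchors(filtered, genes)
    counts["synteny_anchors"] = len(synteny_anchors)

    marker_report: dict[str, int] = {}
    genetic_anchors: list[AnchorPoint] = []
    if markers:
        genetic_anchors, marker_report = anchor_maps.build_marker_anchors(
            flank_hits, markers, min_identity=min_marker_identity
        )
    else:
        logger.warning("no marker map supplied; running synteny-only")
    counts["genetic_anchors"] = len(genetic_anchors)

    anchors = synteny_anchors + genetic_anchors
    breakpoints = chimera.detect_chimeric_contigs(anchors, chunk_params)
    counts["breakpoints"] = len(breakpoints)
    split_contigs, anchors, name_map = chimera.split_and_remap(
        contigs, anchors, breakpoints
    )
    counts["contigs_after_split"] = len(split_contigs)
    counts["anchors"] = len(anchors)

    contig_lengths = {c.id: len(c) for c in split_contigs}
    assignment = scaffolder.assign_linkage_groups(anchors, weights)
    counts["contigs_assigned"] = len(assignment)
    layout = scaffolder.order_and_orient(
        anchors,
        assignment,
        contig_lengths,
        weights,
        within_gap=within_gap,
        unplaced_gap=unplaced_gap,
    )
    records, agp_rows = scaffolder.build_pseudomolecules(layout, split_contigs)
    stats = scaffolder.assembly_stats(split_contigs, layout)
    return PipelineResult(
        layout=layout,
        breakpoints=breakpoints,
        anchors=anchors,
        contigs=split_contigs,
        name_map=name_map,
        records=records,
        agp_rows=agp_rows,
        stats=stats,
        counts=counts,
        marker_report=marker_report,
    )


def run_scaffold_files(config: PipelineConfig) -> PipelineResult:
    """File-based pipeline: parse inputs, run, write the output bundle."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    contigs = stage("parse_contigs", formats_io.parse_sequences, config.contigs)
    genes = stage("parse_gene_models", formats_io.parse_gene_models, config.gene_models)
    hits = stage("parse_hits", formats_io.parse_hits, config.hits)
    markers: list[MarkerRecord] = []
    flanks: list[TabularHit] = []
    if config.marker_map:
        markers = stage("parse_marker_map", anchor_maps.read_marker_map, config.marker_map)
        flanks = stage("parse_flank_hits", formats_io.parse_hits, config.flank_hits)

    result = run_scaffold_pipeline(
        contigs,
        genes,
        hits,
        markers,
        flanks,
        filter_params=config.filter_params,
        chunk_params=config.chunk_params,
        weights=config.weights,
        within_gap=config.within_gap,
        unplaced_gap=config.unplaced_gap,
        min_marker_identity=config.min_marker_identity,
    )

    anchor_maps.write_anchors(result.anchors, out / "anchors.csv")
    chimera.write_breakpoints(result.breakpoints, out / "breakpoints.tsv")
    chimera.write_name_map(result.name_map, out / "name_map.tsv")
    formats_io.write_sequences(result.records, out / "pseudomolecules.fa")
    formats_io.write_agp(result.agp_rows, out / "scaffolds.agp")
    scaffolder.write_placement_table(result.layout, out / "placement.tsv")
    (out / "stats.json").write_text(result.stats.to_json())
    manifest = {
        "parameters": {
            "filter_params": dataclasses.asdict(config.filter_params),
            "chunk_params": dataclasses.asdict(config.chunk_params),
            "weights": config.weights,
            "within_gap": config.within_gap,
            "unplaced_gap": config.unplaced_gap,
            "min_marker_identity": config.min_marker_identity,
        },
        "counts": result.counts,
        "marker_report": result.marker_report,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    for name, value in sorted(result.counts.items()):
        logger.info("%s: %d", name, value)
    return result
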