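"""Construction of the two anchor maps that drive scaffolding.

The synteny map ties contigs to reference chromosomes through best BLAST-style
hits of reference gene models; the genetic map ties them to linkage groups
through SNP-marker flank alignments.  An anchor point is a
(contig position <-> map position) correspondence — the atom of evidence the
scaffolder consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import GeneModel, TabularHit

__all__ = [
    "AnchorPoint",
    "MarkerRecord",
    "FilterParams",
    "rank_reference_genes",
    "select_best_hits",
    "filter_spurious_runs",
    "build_synteny_anchors",
    "build_marker_anchors",
    "read_marker_map",
    "write_marker_map",
    "read_anchors",
    "write_anchors",
]

logger = logging.getLogger(__name__)

SYNTENY = "synteny"
GENETIC = "genetic"


@dataclass(frozen=True)
class AnchorPoint:
    """One contig-to-map correspondence.

    ``map_pos`` is a reference bp coordinate for the synteny map and a cM
    position for the genetic map; the scaffolder rank-normalizes per map, so
    the two units never mix directly.
    """

    contig_id: str
    contig_pos: int  # 0-based bp on the contig
    linkage_group: str
    map_pos: float
    map_name: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("anchor weight must be > 0")
        if self.contig_pos < 0:
            raise ValueError("contig_pos must be >= 0")


@dataclass(frozen=True)
class MarkerRecord:
    """A genetic-map marker with its SNP flank geometry."""

    marker_id: str
    linkage_group: str
    map_pos: float  # cM
    flank_length: int = 200
    snp_offset: int = 100

    def __post_init__(self) -> None:
        if not 0 <= self.snp_offset < self.flank_length:
            raise ValueError(
                f"marker {self.marker_id}: snp_offset {self.snp_offset} outside "
                f"flank of length {self.flank_length}"
            )


@dataclass(frozen=True)
class FilterParams:
    """Spurious-hit run filter: on contigs with at least ``min_hits_for_filter``
    hits, runs of one reference chromosome no longer than
    ``spurious_run_length`` are removed."""

    min_hits_for_filter: int = 3
    spurious_run_length: int = 1

    def __post_init__(self) -> None:
        if self.min_hits_for_filter < 1:
            raise ValueError("min_hits_for_filter must be >= 1")
        if self.spurious_run_length < 0:
            raise ValueError("spurious_run_length must be >= 0")


def rank_reference_genes(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Number genes 1..n per chromosome by ascending start (ties by gene id).

    Returns a DataFrame with columns chromosome, gene_id, isoform_id, start,
    stop, strand, rank — the shared rank space for synteny-chain detection.
    """
    df = pd.DataFrame(
        [
            (g.chromosome, g.gene_id, g.isoform_id, g.start, g.stop, g.strand)
            for g in genes
        ],
        columns=["chromosome", "gene_id", "isoform_id", "start", "stop", "strand"],
    )
    df = df.sort_values(["chromosome", "start", "gene_id"], kind="stable").reset_index(
        drop=True
    )
    df["rank"] = df.groupby("chromosome").cumcount() + 1
    return df


def select_best_hits(hits: Iterable[TabularHit]) -> dict[str, TabularHit]:
    """One best hit per query: max bitscore, then longer alignment, then
    lexicographically smaller subject id."""
    best: dict[str, TabularHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        a = (h.bitscore, h.aln_length)
        b = (cur.bitscore, cur.aln_length)
        if a > b or (a == b and h.subject_id < cur.subject_id):
            best[h.query_id] = h
    return best


def _contig_sorted(hits: Iterable[TabularHit]) -> dict[str, list[TabularHit]]:
    by_contig: dict[str, list[TabularHit]] = {}
    for h in hits:
        by_contig.setdefault(h.subject_id, []).append(h)
    for contig in by_contig:
        by_contig[contig].sort(key=lambda h: (h.subject_start, h.subject_end, h.query_id))
    return by_contig


def filter_spurious_runs(
    hits: Iterable[TabularHit],
    chromosome_of: Mapping[str, str],
    params: FilterParams = FilterParams(),
) -> list[TabularHit]:
    """Drop isolated wrong-chromosome hits from well-covered contigs.

    Hits on each contig are ordered by contig coordinate; maximal runs of the
    same reference chromosome are computed once on that order, and on contigs
    with >= ``min_hits_for_filter`` hits every hit inside a run of length
    <= ``spurious_run_length`` is removed.  Single pass: removals never merge
    flanking runs into new removable runs.
    """
    by_contig = _contig_sorted(hits)
    kept: list[TabularHit] = []
    for contig in by_contig:
        contig_hits = by_contig[contig]
        if len(contig_hits) < params.min_hits_for_filter:
            kept.extend(contig_hits)
            continue
        labels = [chromosome_of[h.query_id] for h in contig_hits]
        i = 0
        while i < len(labels):
            j = i
            while j < len(labels) and labels[j] == labels[i]:
                j += 1
            if j - i > params.spurious_run_length:
                kept.extend(contig_hits[i:j])
            i = j
    return kept


def _anchor_endpoints(hit: TabularHit, gene: GeneModel) -> tuple[int, int]:
    """Contig positions aligned to the gene's start side and stop side."""
    if hit.strand == "+":
        return hit.subject_start, hit.subject_end - 1
    return hit.subject_end - 1, hit.subject_start


def build_synteny_anchors(
    hits: Iterable[TabularHit],
    genes: Iterable[GeneModel],
    weight: float = 1.0,
) -> list[AnchorPoint]:
    """Turn filtered best hits into synteny anchor points.

    Contigs with >= 2 surviving hits contribute one anchor per hit at the
    gene-model start coordinate; contigs with exactly one hit contribute two
    anchors (gene start and gene stop, at the matching alignment endpoints)
    so the single hit can still orient the contig.
    """
    by_isoform = {g.isoform_id: g for g in genes}
    by_contig = _contig_sorted(hits)
    anchors: list[AnchorPoint] = []
    for contig in sorted(by_contig):
        contig_hits = by_contig[contig]
        for h in contig_hits:
            if h.query_id not in by_isoform:
                raise KeyError(f"hit query {h.query_id} not among gene models")
        if len(contig_hits) == 1:
            h = contig_hits[0]
            g = by_isoform[h.query_id]
            start_pos, stop_pos = _anchor_endpoints(h, g)
            anchors.append(
                AnchorPoint(contig, start_pos, g.chromosome, float(g.start), SYNTENY, weight)
            )
            anchors.append(
                AnchorPoint(contig, stop_pos, g.chromosome, float(g.stop), SYNTENY, weight)
            )
        else:
            for h in contig_hits:
                g = by_isoform[h.query_id]
                start_pos, _ = _anchor_endpoints(h, g)
                anchors.append(
                    AnchorPoint(
                        contig, start_pos, g.chromosome, float(g.start), SYNTENY, weight
                    )
                )
    return anchors


def build_marker_anchors(
    flank_hits: Iterable[TabularHit],
    markers: Iterable[MarkerRecord],
    min_identity: float = 95.0,
    bitscore_margin: float = 10.0,
    weight: float = 1.0,
) -> tuple[list[AnchorPoint], dict[str, int]]:
    """Place genetic-map markers on contigs through their flank alignments.

    A marker anchors only if it has a unique best placement: highest bitscore
    among hits with identity >= ``min_identity``, with no runner-up within
    ``bitscore_margin`` bitscore units (near-repeats disqualify).  The SNP
    position inside the flank is projected through the alignment,
    strand-aware.  Returns (anchors, report) where report counts markers
    placed / ambiguous / unaligned / offset_outside.
    """
    marker_list = list(markers)
    by_marker: dict[str, list[TabularHit]] = {m.marker_id: [] for m in marker_list}
    for h in flank_hits:
        if h.query_id in by_marker and h.pct_identity >= min_identity:
            by_marker[h.query_id].append(h)

    anchors: list[AnchorPoint] = []
    report = {"placed": 0, "ambiguous": 0, "unaligned": 0, "offset_outside": 0}
    for marker in marker_list:
        cands = sorted(
            by_marker[marker.marker_id],
            key=lambda h: (-h.bitscore, -h.aln_length, h.subject_id, h.subject_start),
        )
        if not cands:
            report["unaligned"] += 1
            continue
        best = cands[0]
        if len(cands) > 1 and cands[1].bitscore >= best.bitscore - bitscore_margin:
            report["ambiguous"] += 1
            continue
        if not best.query_start <= marker.snp_offset < best.query_end:
            logger.warning(
                "marker %s: SNP offset %d outside aligned flank interval [%d,%d)",
                marker.marker_id,
                marker.snp_offset,
                best.query_start,
                best.query_end,
            )
            report["offset_outside"] += 1
            continue
        delta = marker.snp_offset - best.query_start
        if best.strand == "+":
            pos = best.subject_start + delta
        else:
            pos = best.subject_end - 1 - delta
        anchors.append(
            AnchorPoint(
                best.subject_id,
                pos,
                marker.linkage_group,
                float(marker.map_pos),
                GENETIC,
                weight,
            )
        )
        report["placed"] += 1
    return anchors, report


# ---------------------------------------------------------------------------
# CSV interchange


def read_marker_map(path: str | Path) -> list[MarkerRecord]:
    df = pd.read_csv(path)
    return [
        MarkerRecord(
            marker_id=str(r.marker_id),
            linkage_group=str(r.linkage_group),
            map_pos=float(r.cM),
            flank_length=int(getattr(r, "flank_length", 200)),
            snp_offset=int(r.snp_offset),
        )
        for r in df.itertuples(index=False)
    ]


def write_marker_map(markers: Iterable[MarkerRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (m.marker_id, m.linkage_group, m.map_pos, m.flank_length, m.snp_offset)
            for m in markers
        ],
        columns=["marker_id", "linkage_group", "cM", "flank_length", "snp_offset"],
    ).to_csv(path, index=False)


def write_anchors(anchors: Sequence[AnchorPoint], path: str | Path) -> None:
    """Anchor CSV, sorted by contig then position (stable interchange form)."""
    rows = sorted(
        anchors, key=lambda a: (a.contig_id, a.contig_pos, a.map_name, a.map_pos)
    )
    pd.DataFrame(
        [
            (a.contig_id, a.contig_pos, a.linkage_group, a.map_pos, a.map_name, a.weight)
            for a in rows
        ],
        columns=["contig_id", "contig_pos", "linkage_group", "map_pos", "map_name", "weight"],
    ).to_csv(path, index=False)


def read_anchors(path: str | Path) -> list[AnchorPoint]:
    df = pd.read_csv(path)
    return [
        AnchorPoint(
            str(r.contig_id),
            int(r.contig_pos),
            str(r.linkage_group),
            float(r.map_pos),
            str(r.map_name),
            float(r.weight),
        )
        for r in df.itertuples(index=False)
    ]
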