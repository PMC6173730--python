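"""Detection and splitting of chimeric (mis-joined) contigs.

A contig whose ordered anchors switch from a long run of one linkage group to
a long run of another was almost certainly mis-joined by the assembler.  Both
anchor maps are pooled; runs shorter than ``chunk`` are treated as noise and
skipped (not merged into their neighbours).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .anchor_maps import AnchorPoint
from .formats_io import SeqRecord

__all__ = ["Breakpoint", "ChunkParams", "detect_chimeric_contigs", "split_and_remap",
           "write_breakpoints", "write_name_map"]


@dataclass(frozen=True)
class Breakpoint:
    """A split point inside a contig: the split occurs before ``position``."""

    contig_id: str
    position: int  # 0-based bp
    left_group: str
    right_group: str
    left_support: int
    right_support: int


@dataclass(frozen=True)
class ChunkParams:
    chunk: int = 4

    def __post_init__(self) -> None:
        if self.chunk < 2:
            raise ValueError("chunk must be >= 2")


def _runs(labels: list[str]) -> list[tuple[str, int, int]]:
    """Maximal runs as (label, start_index, end_index_exclusive)."""
    runs = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        runs.append((labels[i], i, j))
        i = j
    return runs


def detect_chimeric_contigs(
    anchors: Iterable[AnchorPoint], params: ChunkParams = ChunkParams()
) -> list[Breakpoint]:
    """Scan each contig's ordered anchors for linkage-group conflicts.

    Every adjacent pair of maximal runs with different groups and both run
    lengths >= ``chunk`` yields one breakpoint at the (floored) midpoint
    between the last anchor of the left run and the first anchor of the
    right run.
    """
    by_contig: dict[str, list[AnchorPoint]] = {}
    for a in anchors:
        by_contig.setdefault(a.contig_id, []).append(a)
    breakpoints: list[Breakpoint] = []
    for contig in sorted(by_contig):
        ordered = sorted(by_contig[contig], key=lambda a: (a.contig_pos, a.map_pos))
        labels = [a.linkage_group for a in ordered]
        big = [(lbl, i, j) for lbl, i, j in _runs(labels) if j - i >= params.chunk]
        for (l_lbl, l_start, l_end), (r_lbl, r_start, r_end) in zip(big, big[1:]):
            if l_lbl == r_lbl:
                continue
            left_anchor = ordered[l_end - 1]
            right_anchor = ordered[r_start]
            pos = (left_anchor.contig_pos + right_anchor.contig_pos) // 2
            breakpoints.append(
                Breakpoint(
                    contig_id=contig,
                    position=pos,
                    left_group=l_lbl,
                    right_group=r_lbl,
                    left_support=l_end - l_start,
                    right_support=r_end - r_start,
                )
            )
    return breakpoints


def split_and_remap(
    contigs: Iterable[SeqRecord],
    anchors: Iterable[AnchorPoint],
    breakpoints: Iterable[Breakpoint],
) -> tuple[list[SeqRecord], list[AnchorPoint], dict[str, list[tuple[str, int, int]]]]:
    """Split contigs at breakpoints and shift their anchors onto the parts.

    A contig with k breakpoints becomes parts ``<id>_part1 .. <id>_part{k+1}``
    in coordinate order; bases are partitioned exactly and each anchor moves to
    the part containing it with its position shifted by the part offset.
    Returns (new contigs, remapped anchors, name map old -> [(new, start, end)]).
    """
    bp_by_contig: dict[str, list[int]] = {}
    for bp in breakpoints:
        bp_by_contig.setdefault(bp.contig_id, []).append(bp.position)

    new_contigs: list[SeqRecord] = []
    name_map: dict[str, list[tuple[str, int, int]]] = {}
    for rec in contigs:
        cuts = sorted(set(bp_by_contig.get(rec.id, [])))
        if not cuts:
            new_contigs.append(rec)
            name_map[rec.id] = [(rec.id, 0, len(rec))]
            continue
        for c in cuts:
            if not 0 < c < len(rec):
                raise ValueError(
                    f"breakpoint {c} outside the interior of contig {rec.id} "
                    f"(length {len(rec)})"
                )
        bounds = [0] + cuts + [len(rec)]
        segments = []
        for k, (s, e) in enumerate(zip(bounds, bounds[1:]), start=1):
            part_id = f"{rec.id}_part{k}"
            new_contigs.append(SeqRecord(part_id, rec.sequence[s:e]))
            segments.append((part_id, s, e))
        name_map[rec.id] = segments

    remapped: list[AnchorPoint] = []
    for a in anchors:
        segments = name_map.get(a.contig_id)
        if segments is None or len(segments) == 1:
            remapped.append(a)
            continue
        for part_id, s, e in segments:
            if s <= a.contig_pos < e:
                remapped.append(
                    AnchorPoint(
                        part_id,
                        a.contig_pos - s,
                        a.linkage_group,
                        a.map_pos,
                        a.map_name,
                        a.weight,
                    )
                )
                break
        else:  # pragma: no cover - positions are always < contig length
            raise ValueError(f"anchor at {a.contig_pos} beyond contig {a.contig_id}")
    return new_contigs, remapped, name_map


def write_breakpoints(breakpoints: Iterable[Breakpoint], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tposition\tleft_group\tright_group\tleft_support\tright_support\n")
        for b in breakpoints:
            fh.write(
                f"{b.contig_id}\t{b.position}\t{b.left_group}\t{b.right_group}"
                f"\t{b.left_support}\t{b.right_support}\n"
            )


def write_name_map(name_map: Mapping[str, list[tuple[str, int, int]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("old_id\tnew_id\tstart\tend\n")
        for old in sorted(name_map):
            for new, s, e in name_map[old]:
                fh.write(f"{old}\t{new}\t{s}\t{e}\n")
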