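"""Readers and writers for the standard formats the toolkit touches.

Every coordinate held in memory is 0-based, half-open.  The 1-based,
inclusive conventions of FASTA-adjacent formats (GFF3, AGP, 12-column
tabular alignments) are converted at the parse/write boundary and nowhere
else.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import gffutils.iterators
from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "TabularHit",
    "GeneModel",
    "AgpRow",
    "ScaffoldLayout",
    "parse_sequences",
    "write_sequences",
    "parse_hits",
    "write_hits",
    "parse_gene_models",
    "read_agp",
    "write_agp",
    "layout_to_agp",
    "agp_to_layout",
    "reconstruct_from_agp",
    "read_bed_features",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence; the unit being ordered and oriented."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TabularHit:
    """One pairwise alignment record (a BLAST/bwa-style local hit).

    Coordinates are 0-based half-open on both query and subject;
    ``strand`` is "-" when the original record had subject start > end.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be >= 1, got {self.aln_length}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of [0,100]: {self.pct_identity}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue: {self.evalue}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its representative (first-appearing) isoform.

    ``start``/``stop`` are the gene's genomic coordinates, 0-based half-open.
    """

    gene_id: str
    isoform_id: str
    chromosome: str
    start: int
    stop: int
    strand: str
    isoform_order: int = 1

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"{self.gene_id}: start must be < stop")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be +/-")


@dataclass(frozen=True)
class AgpRow:
    """One AGP 2.1 line. Object coordinates 1-based inclusive (file convention)."""

    object_id: str
    object_start: int
    object_end: int
    part_number: int
    component_type: str  # "W" contig, "N" gap
    component_id: str | None = None
    component_start: int | None = None
    component_end: int | None = None
    orientation: str | None = None
    gap_length: int | None = None
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "map"


@dataclass
class ScaffoldLayout:
    """Ordered, oriented contigs per linkage group plus the unplaced pool."""

    groups: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    unplaced: list[str] = field(default_factory=list)
    within_gap: int = 100
    unplaced_gap: int = 1000
    unplaced_name: str = "unplaced"

    def placed_contigs(self) -> list[str]:
        return [cid for placements in self.groups.values() for cid, _ in placements]


# ---------------------------------------------------------------------------
# FASTA


def parse_sequences(source: str | Path | TextIO) -> list[SeqRecord]:
    """Read FASTA into SeqRecords (order preserved, sequence upper-cased).

    Duplicate ids and empty sequence bodies are errors; empty input yields
    an empty list.
    """
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        records: list[SeqRecord] = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id: {rec.id}")
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"empty sequence body for id: {rec.id}")
            seen.add(rec.id)
            records.append(SeqRecord(rec.id, seq))
        return records
    finally:
        if isinstance(source, (str, Path)):
            handle.close()


def write_sequences(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# 12-column tabular alignments ("outfmt 6") and PAF


def _parse_tab12_line(fields: list[str], lineno: int) -> TabularHit:
    (qid, sid, pident, length, _mm, _go, qs, qe, ss, se, ev, bs) = fields
    qs_i, qe_i, ss_i, se_i = int(qs), int(qe), int(ss), int(se)
    strand = "+" if ss_i <= se_i else "-"
    lo, hi = min(ss_i, se_i), max(ss_i, se_i)
    return TabularHit(
        query_id=qid,
        subject_id=sid,
        pct_identity=float(pident),
        aln_length=int(length),
        query_start=min(qs_i, qe_i) - 1,
        query_end=max(qs_i, qe_i),
        subject_start=lo - 1,
        subject_end=hi,
        strand=strand,
        evalue=float(ev),
        bitscore=float(bs),
    )


def _parse_paf_line(fields: list[str], lineno: int) -> TabularHit:
    qid, _qlen, qs, qe, strand, tid, _tlen, ts, te, nmatch, alnlen = fields[:11]
    alnlen_i = int(alnlen)
    return TabularHit(
        query_id=qid,
        subject_id=tid,
        pct_identity=100.0 * int(nmatch) / max(alnlen_i, 1),
        aln_length=alnlen_i,
        query_start=int(qs),
        query_end=int(qe),
        subject_start=int(ts),
        subject_end=int(te),
        strand=strand,
        evalue=0.0,
        bitscore=float(nmatch),
    )


def parse_hits(source: str | Path | TextIO, dialect: str = "tab12") -> list[TabularHit]:
    """Parse an alignment table in the 12-column tabular or PAF dialect.

    Minus-strand subject intervals are normalized to start < end with the
    original orientation kept in ``strand``.  A line with the wrong column
    count raises a ValueError naming the line number.
    """
    if dialect not in ("tab12", "paf"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        hits: list[TabularHit] = []
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "tab12":
                if len(fields) != 12:
                    raise ValueError(
                        f"line {lineno}: expected 12 columns, got {len(fields)}"
                    )
                hits.append(_parse_tab12_line(fields, lineno))
            else:
                if len(fields) < 12:
                    raise ValueError(
                        f"line {lineno}: expected >= 12 PAF columns, got {len(fields)}"
                    )
                hits.append(_parse_paf_line(fields, lineno))
        return hits
    finally:
        if isinstance(source, (str, Path)):
            handle.close()


def write_hits(hits: Iterable[TabularHit], path: str | Path) -> None:
    """Write hits back out as 12-column tabular (1-based, strand via swapped subject)."""
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                ss, se = h.subject_start + 1, h.subject_end
            else:
                ss, se = h.subject_end, h.subject_start + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        h.aln_length,
                        0,
                        0,
                        h.query_start + 1,
                        h.query_end,
                        ss,
                        se,
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene models


def parse_gene_models(source: str | Path | TextIO) -> list[GeneModel]:
    """Read GFF3 gene models, keeping the first-appearing isoform per gene.

    "First isoform" means the first mRNA encountered in file order for the
    gene (annotation files list the representative transcript first); a gene
    without mRNA children represents itself.  GFF3 1-based inclusive
    coordinates become 0-based half-open.
    """
    if isinstance(source, (str, Path)):
        feature_iter = gffutils.iterators.DataIterator(str(source))
    else:
        feature_iter = gffutils.iterators.DataIterator(source.read(), from_string=True)

    genes: dict[str, GeneModel] = {}
    order: list[str] = []
    isoform_counts: dict[str, int] = {}
    for feat in feature_iter:
        if feat.featuretype == "gene":
            gid = feat.attributes.get("ID", [feat.id])[0]
            if feat.strand not in ("+", "-"):
                raise ValueError(f"gene {gid}: missing strand")
            genes[gid] = GeneModel(
                gene_id=gid,
                isoform_id=gid,
                chromosome=feat.seqid,
                start=feat.start - 1,
                stop=feat.end,
                strand=feat.strand,
                isoform_order=0,
            )
            order.append(gid)
        elif feat.featuretype == "mRNA":
            parents = feat.attributes.get("Parent", [])
            if not parents or parents[0] not in genes:
                raise ValueError(
                    f"mRNA {feat.attributes.get('ID', ['?'])[0]} has no parent gene"
                )
            gid = parents[0]
            isoform_counts[gid] = isoform_counts.get(gid, 0) + 1
            if genes[gid].isoform_order == 0:  # first mRNA wins
                mid = feat.attributes.get("ID", [feat.id])[0]
                genes[gid] = replace(genes[gid], isoform_id=mid, isoform_order=1)
    out = []
    for gid in order:
        g = genes[gid]
        out.append(replace(g, isoform_order=1) if g.isoform_order == 0 else g)
    return out


# ---------------------------------------------------------------------------
# AGP 2.1


def write_agp(rows: Iterable[AgpRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        for r in rows:
            if r.component_type == "W":
                fields = [
                    r.object_id,
                    r.object_start,
                    r.object_end,
                    r.part_number,
                    "W",
                    r.component_id,
                    r.component_start,
                    r.component_end,
                    r.orientation,
                ]
            else:
                fields = [
                    r.object_id,
                    r.object_start,
                    r.object_end,
                    r.part_number,
                    "N",
                    r.gap_length,
                    r.gap_type,
                    r.linkage,
                    r.evidence,
                ]
            fh.write("\t".join(str(x) for x in fields) + "\n")


def read_agp(source: str | Path | TextIO) -> list[AgpRow]:
    """Read AGP rows and check that rows tile each object without gaps."""
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        rows: list[AgpRow] = []
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"AGP line {lineno}: expected 9 columns, got {len(f)}")
            base = dict(
                object_id=f[0],
                object_start=int(f[1]),
                object_end=int(f[2]),
                part_number=int(f[3]),
                component_type=f[4],
            )
            if f[4] == "W":
                rows.append(
                    AgpRow(
                        **base,
                        component_id=f[5],
                        component_start=int(f[6]),
                        component_end=int(f[7]),
                        orientation=f[8],
                    )
                )
            elif f[4] == "N":
                rows.append(
                    AgpRow(**base, gap_length=int(f[5]), gap_type=f[6], linkage=f[7], evidence=f[8])
                )
            else:
                raise ValueError(f"AGP line {lineno}: component_type {f[4]!r} unsupported")
    finally:
        if isinstance(source, (str, Path)):
            handle.close()

    expected: dict[str, int] = {}
    for r in rows:
        nxt = expected.get(r.object_id, 1)
        if r.object_start != nxt:
            raise ValueError(
                f"AGP rows do not tile object {r.object_id}: part {r.part_number} "
                f"starts at {r.object_start}, expected {nxt}"
            )
        span = r.object_end - r.object_start + 1
        if r.component_type == "W":
            if span != r.component_end - r.component_start + 1:
                raise ValueError(
                    f"AGP W row span mismatch on {r.object_id} part {r.part_number}"
                )
        elif span != r.gap_length:
            raise ValueError(f"AGP N row span != gap_length on {r.object_id}")
        expected[r.object_id] = r.object_end + 1
    return rows


def layout_to_agp(layout: ScaffoldLayout, contig_lengths: dict[str, int]) -> list[AgpRow]:
    """Serialize a layout as AGP 2.1 rows (W contig rows, N scaffold gaps)."""
    rows: list[AgpRow] = []

    def emit(obj: str, contigs: Sequence[tuple[str, str]], gap: int) -> None:
        pos = 1
        part = 1
        for i, (cid, ori) in enumerate(contigs):
            if cid not in contig_lengths:
                raise KeyError(f"layout contig {cid} has no length/sequence")
            clen = contig_lengths[cid]
            if i > 0 and gap > 0:
                rows.append(
                    AgpRow(obj, pos, pos + gap - 1, part, "N", gap_length=gap)
                )
                pos += gap
                part += 1
            rows.append(
                AgpRow(obj, pos, pos + clen - 1, part, "W", cid, 1, clen, ori)
            )
            pos += clen
            part += 1

    for group in sorted(layout.groups):
        emit(group, layout.groups[group], layout.within_gap)
    if layout.unplaced:
        emit(layout.unplaced_name, [(cid, "+") for cid in layout.unplaced], layout.unplaced_gap)
    return rows


def agp_to_layout(rows: Iterable[AgpRow], unplaced_name: str = "unplaced") -> ScaffoldLayout:
    layout = ScaffoldLayout(unplaced_name=unplaced_name)
    for r in rows:
        if r.component_type == "N":
            if r.object_id == unplaced_name:
                layout.unplaced_gap = r.gap_length or layout.unplaced_gap
            else:
                layout.within_gap = r.gap_length or layout.within_gap
            continue
        if r.object_id == unplaced_name:
            layout.unplaced.append(r.component_id)
        else:
            layout.groups.setdefault(r.object_id, []).append((r.component_id, r.orientation))
    return layout


def reconstruct_from_agp(rows: Iterable[AgpRow], contigs: dict[str, str]) -> list[SeqRecord]:
    """Rebuild object sequences from AGP rows plus component sequences."""
    parts: dict[str, list[str]] = {}
    order: list[str] = []
    for r in rows:
        if r.object_id not in parts:
            parts[r.object_id] = []
            order.append(r.object_id)
        if r.component_type == "N":
            parts[r.object_id].append("N" * r.gap_length)
        else:
            seq = contigs[r.component_id][r.component_start - 1 : r.component_end]
            parts[r.object_id].append(revcomp(seq) if r.orientation == "-" else seq)
    return [SeqRecord(oid, "".join(parts[oid])) for oid in order]


# ---------------------------------------------------------------------------
# BED features


def read_bed_features(source: str | Path | TextIO) -> list[tuple[str, int, int, str, str]]:
    """Read BED as (chrom, start, end, name/label, strand) tuples (0-based half-open)."""
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        out = []
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            name = f[3] if len(f) > 3 else "."
            strand = f[5] if len(f) > 5 else "+"
            out.append((f[0], int(f[1]), int(f[2]), name, strand))
        return out
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
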