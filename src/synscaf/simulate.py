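"""Seeded synthetic datasets with known ground truth.

The generator emulates the inputs of a synteny + genetic-map scaffolding run
on a compact genome: a reference annotation with evenly spaced genes, a
proportional genetic map, contigs obtained by fragmenting (and sometimes
mis-joining) the reference chromosomes, and the alignment tables a BLAST/bwa
step would produce — one best hit per surviving gene plus a controlled rate
of spurious wrong-chromosome hits.  Sequence composition is arbitrary
(repeat-free, uniform ACGT): the toolkit never re-aligns sequence, so only
coordinates matter.  Every artifact is a pure function of the config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import kendalltau

from .anchor_maps import MarkerRecord, write_marker_map
from .chimera import Breakpoint
from .formats_io import (
    GeneModel,
    ScaffoldLayout,
    SeqRecord,
    TabularHit,
    revcomp,
    write_hits,
    write_sequences,
)

__all__ = [
    "SimConfig",
    "Segment",
    "ContigTruth",
    "TruthTable",
    "Reference",
    "simulate_reference",
    "derive_target",
    "emit_observations",
    "simulate_dataset",
    "write_dataset",
    "evaluate_recovery",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 4
    genes_per_chromosome: int = 200
    gene_length: int = 1000
    intergenic: int = 2000
    n_contigs: int = 80
    inversion_rate: float = 0.3
    n_chimeras: int = 3
    spurious_rate: float = 0.02
    marker_count: int = 60
    anchor_missing_rate: float = 0.1
    flank_length: int = 200
    min_chimera_genes: int = 4  # genes per side, so injected mis-joins are detectable

    def __post_init__(self) -> None:
        for rate in (self.inversion_rate, self.spurious_rate, self.anchor_missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.n_contigs < self.n_chromosomes:
            raise ValueError("n_contigs must be >= n_chromosomes")


@dataclass(frozen=True)
class Segment:
    """A reference interval carried by (part of) a contig."""

    chromosome: str
    order_index: int  # index of the source piece along its chromosome
    orientation: str  # "+" as-is, "-" reverse-complemented in the contig
    contig_start: int
    contig_end: int
    chrom_start: int
    chrom_end: int


@dataclass
class ContigTruth:
    contig_id: str
    segments: list[Segment]
    is_chimera: bool
    breakpoints: list[int]  # contig positions


@dataclass
class TruthTable:
    contigs: dict[str, ContigTruth]
    chrom_lengths: dict[str, int]

    def true_breakpoints(self) -> list[tuple[str, int]]:
        return [
            (c.contig_id, bp) for c in self.contigs.values() for bp in c.breakpoints
        ]


@dataclass
class Reference:
    chromosomes: dict[str, str]
    genes: list[GeneModel]
    markers: list[MarkerRecord]
    marker_positions: dict[str, tuple[str, int]]  # marker -> (chromosome, SNP bp)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _rngs(config: SimConfig) -> tuple[np.random.Generator, ...]:
    # one seed, fixed per-stage substreams
    children = np.random.SeedSequence(config.seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def simulate_reference(config: SimConfig) -> Reference:
    """Reference chromosomes with evenly spaced genes and a proportional map.

    Gene i on each chromosome occupies
    [intergenic + i*(gene_length+intergenic), ... + gene_length); markers sit
    at uniform random gene-free positions with cM proportional to bp
    (4 cM/Mb, the usual plant-genome scale).
    """
    rng = _rngs(config)[0]
    step = config.gene_length + config.intergenic
    chrom_len = config.genes_per_chromosome * step + config.intergenic
    chromosomes: dict[str, str] = {}
    genes: list[GeneModel] = []
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        chromosomes[chrom] = _random_seq(rng, chrom_len)
        for i in range(config.genes_per_chromosome):
            start = config.intergenic + i * step
            gid = f"g_{chrom}_{i:04d}"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    isoform_id=f"{gid}.1",
                    chromosome=chrom,
                    start=start,
                    stop=start + config.gene_length,
                    strand="+",
                )
            )

    markers: list[MarkerRecord] = []
    marker_positions: dict[str, tuple[str, int]] = {}
    half = config.flank_length // 2
    per_chrom = [
        config.marker_count // config.n_chromosomes
        + (1 if c < config.marker_count % config.n_chromosomes else 0)
        for c in range(config.n_chromosomes)
    ]
    for c, count in enumerate(per_chrom, start=1):
        chrom = f"chr{c}"
        used: set[int] = set()
        for j in range(count):
            while True:
                region = int(rng.integers(0, config.genes_per_chromosome + 1))
                lo = region * step + half
                hi = region * step + config.intergenic - half
                pos = int(rng.integers(lo, hi))
                if pos not in used:
                    used.add(pos)
                    break
            mid = f"m_{chrom}_{j:03d}"
            markers.append(
                MarkerRecord(
                    marker_id=mid,
                    linkage_group=chrom,
                    map_pos=round(pos * 4.0 / 1e6, 6),  # 4 cM / Mb
                    flank_length=config.flank_length,
                    snp_offset=half,
                )
            )
            marker_positions[mid] = (chrom, pos)
    return Reference(chromosomes, genes, markers, marker_positions)


def derive_target(
    reference: Reference, config: SimConfig
) -> tuple[list[SeqRecord], TruthTable]:
    """Fragment the reference into contigs with inversions and chimeric joins.

    Chromosomes are cut at random inter-gene boundaries (the midpoint of an
    intergenic region); each piece is independently reverse-complemented with
    ``inversion_rate``; ``n_chimeras`` pairs of pieces from different
    chromosomes (each carrying >= ``min_chimera_genes`` genes) are
    concatenated with the join position recorded as the true breakpoint.
    """
    rng = _rngs(config)[1]
    step = config.gene_length + config.intergenic
    chrom_names = sorted(reference.chromosomes)
    n = config.n_chromosomes
    per_chrom = [
        config.n_contigs // n + (1 if c < config.n_contigs % n else 0) for c in range(n)
    ]

    pieces: list[dict] = []
    for chrom, n_pieces in zip(chrom_names, per_chrom):
        length = len(reference.chromosomes[chrom])
        n_boundaries = config.genes_per_chromosome - 1
        cut_idx = sorted(
            rng.choice(n_boundaries, size=min(n_pieces - 1, n_boundaries), replace=False)
        )
        cuts = [int((i + 1) * step + config.intergenic // 2) for i in cut_idx]
        bounds = [0] + cuts + [length]
        for k, (s, e) in enumerate(zip(bounds, bounds[1:])):
            orientation = "-" if rng.random() < config.inversion_rate else "+"
            seq = reference.chromosomes[chrom][s:e]
            pieces.append(
                {
                    "chromosome": chrom,
                    "order_index": k,
                    "orientation": orientation,
                    "chrom_start": s,
                    "chrom_end": e,
                    "sequence": revcomp(seq) if orientation == "-" else seq,
                    "n_genes": sum(
                        1
                        for g in reference.genes
                        if g.chromosome == chrom and s <= g.start and g.stop <= e
                    ),
                }
            )

    # pick chimera partners: pieces from different chromosomes, gene-rich sides
    eligible = [
        i for i, p in enumerate(pieces) if p["n_genes"] >= config.min_chimera_genes
    ]
    rng.shuffle(eligible)
    chimera_pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    for i in eligible:
        if len(chimera_pairs) >= config.n_chimeras:
            break
        if i in used:
            continue
        partner = next(
            (
                j
                for j in eligible
                if j not in used and j != i and pieces[j]["chromosome"] != pieces[i]["chromosome"]
            ),
            None,
        )
        if partner is None:
            continue
        used.update((i, partner))
        chimera_pairs.append((i, partner))

    units: list[ContigTruth] = []
    seqs: list[str] = []
    for i, p in enumerate(pieces):
        if i in used:
            continue
        units.append(
            ContigTruth(
                contig_id="",
                segments=[
                    Segment(
                        p["chromosome"], p["order_index"], p["orientation"],
                        0, len(p["sequence"]), p["chrom_start"], p["chrom_end"],
                    )
                ],
                is_chimera=False,
                breakpoints=[],
            )
        )
        seqs.append(p["sequence"])
    for i, j in chimera_pairs:
        left, right = pieces[i], pieces[j]
        bp = len(left["sequence"])
        units.append(
            ContigTruth(
                contig_id="",
                segments=[
                    Segment(
                        left["chromosome"], left["order_index"], left["orientation"],
                        0, bp, left["chrom_start"], left["chrom_end"],
                    ),
                    Segment(
                        right["chromosome"], right["order_index"], right["orientation"],
                        bp, bp + len(right["sequence"]),
                        right["chrom_start"], right["chrom_end"],
                    ),
                ],
                is_chimera=True,
                breakpoints=[bp],
            )
        )
        seqs.append(left["sequence"] + right["sequence"])

    order = rng.permutation(len(units))
    contigs: list[SeqRecord] = []
    truth: dict[str, ContigTruth] = {}
    for rank, idx in enumerate(order):
        cid = f"ctg{rank + 1:04d}"
        units[idx].contig_id = cid
        contigs.append(SeqRecord(cid, seqs[idx]))
        truth[cid] = units[idx]
    table = TruthTable(
        contigs=truth,
        chrom_lengths={c: len(s) for c, s in reference.chromosomes.items()},
    )
    return contigs, table


def _gene_location(
    gene: GeneModel, truth: TruthTable
) -> tuple[str, Segment] | None:
    for c in truth.contigs.values():
        for seg in c.segments:
            if (
                seg.chromosome == gene.chromosome
                and seg.chrom_start <= gene.start
                and gene.stop <= seg.chrom_end
            ):
                return c.contig_id, seg
    return None


def emit_observations(
    reference: Reference,
    contigs: Sequence[SeqRecord],
    truth: TruthTable,
    config: SimConfig,
) -> tuple[list[TabularHit], list[TabularHit]]:
    """Gene-vs-contig hits and marker flank hits as an aligner would report.

    One correct hit per gene survives with probability
    1 - anchor_missing_rate; round(spurious_rate * n_genes) extra hits are
    injected at random positions on wrong-chromosome contigs with a higher
    bitscore than the true hit, so they win best-hit selection and must be
    caught by the run-length filter downstream.
    """
    rng = _rngs(config)[2]
    gl = config.gene_length
    contig_len = {c.id: len(c) for c in contigs}
    gene_loc = {g.isoform_id: _gene_location(g, truth) for g in reference.genes}

    hits: list[TabularHit] = []
    for g in reference.genes:
        loc = gene_loc[g.isoform_id]
        if loc is None:  # pragma: no cover - cuts never split genes
            continue
        if rng.random() < config.anchor_missing_rate:
            continue
        cid, seg = loc
        if seg.orientation == "+":
            s0 = seg.contig_start + (g.start - seg.chrom_start)
        else:
            s0 = seg.contig_start + (seg.chrom_end - g.stop)
        hits.append(
            TabularHit(
                query_id=g.isoform_id,
                subject_id=cid,
                pct_identity=98.5,
                aln_length=gl,
                query_start=0,
                query_end=gl,
                subject_start=s0,
                subject_end=s0 + gl,
                strand=seg.orientation,
                evalue=1e-180,
                bitscore=2.0 * gl,
            )
        )

    n_spurious = int(round(config.spurious_rate * len(reference.genes)))
    cids = [c.id for c in contigs]
    for _ in range(n_spurious):
        g = reference.genes[int(rng.integers(0, len(reference.genes)))]
        candidates = [
            cid
            for cid in cids
            if g.chromosome
            not in {s.chromosome for s in truth.contigs[cid].segments}
            and contig_len[cid] > gl
        ]
        if not candidates:
            continue
        cid = candidates[int(rng.integers(0, len(candidates)))]
        s0 = int(rng.integers(0, contig_len[cid] - gl))
        hits.append(
            TabularHit(
                query_id=g.isoform_id,
                subject_id=cid,
                pct_identity=97.0,
                aln_length=gl,
                query_start=0,
                query_end=gl,
                subject_start=s0,
                subject_end=s0 + gl,
                strand="+" if rng.random() < 0.5 else "-",
                evalue=1e-170,
                bitscore=3.0 * gl,
            )
        )

    flank_hits: list[TabularHit] = []
    half = config.flank_length // 2
    for m in reference.markers:
        chrom, pos = reference.marker_positions[m.marker_id]
        seg_hit = None
        for c in truth.contigs.values():
            for seg in c.segments:
                if seg.chromosome == chrom and seg.chrom_start <= pos < seg.chrom_end:
                    seg_hit = (c.contig_id, seg)
                    break
            if seg_hit:
                break
        if seg_hit is None:  # pragma: no cover - segments tile chromosomes
            continue
        cid, seg = seg_hit
        f0, f1 = pos - half, pos + half
        a, b = max(f0, seg.chrom_start), min(f1, seg.chrom_end)
        if b - a < half // 2:  # too little of the flank survives the cut
            continue
        if seg.orientation == "+":
            s0 = seg.contig_start + (a - seg.chrom_start)
        else:
            s0 = seg.contig_start + (seg.chrom_end - b)
        flank_hits.append(
            TabularHit(
                query_id=m.marker_id,
                subject_id=cid,
                pct_identity=100.0,
                aln_length=b - a,
                query_start=a - f0,
                query_end=b - f0,
                subject_start=s0,
                subject_end=s0 + (b - a),
                strand=seg.orientation,
                evalue=1e-90,
                bitscore=float(b - a),
            )
        )
    return hits, flank_hits


def simulate_dataset(
    config: SimConfig,
) -> tuple[Reference, list[SeqRecord], TruthTable, list[TabularHit], list[TabularHit]]:
    reference = simulate_reference(config)
    contigs, truth = derive_target(reference, config)
    hits, flank_hits = emit_observations(reference, contigs, truth, config)
    return reference, contigs, truth, hits, flank_hits


def _write_gff3(genes: Iterable[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\tsim\tgene\t{g.start + 1}\t{g.stop}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chromosome}\tsim\tmRNA\t{g.start + 1}\t{g.stop}\t.\t{g.strand}\t.\t"
                f"ID={g.isoform_id};Parent={g.gene_id}\n"
            )


def write_dataset(config: SimConfig, outdir: str | Path) -> None:
    """Materialize a dataset: reference.fa, genes.gff3, contigs.fa, hits.tsv,
    flank_hits.tsv, markers.csv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference, contigs, truth, hits, flank_hits = simulate_dataset(config)
    write_sequences(
        [SeqRecord(c, s) for c, s in sorted(reference.chromosomes.items())],
        outdir / "reference.fa",
    )
    _write_gff3(reference.genes, outdir / "genes.gff3")
    write_sequences(contigs, outdir / "contigs.fa")
    write_hits(hits, outdir / "hits.tsv")
    write_hits(flank_hits, outdir / "flank_hits.tsv")
    write_marker_map(reference.markers, outdir / "markers.csv")
    payload = {
        "config": dataclasses.asdict(config),
        "chrom_lengths": truth.chrom_lengths,
        "contigs": {
            cid: {
                "is_chimera": t.is_chimera,
                "breakpoints": t.breakpoints,
                "segments": [dataclasses.asdict(s) for s in t.segments],
            }
            for cid, t in truth.contigs.items()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_truth(path: str | Path) -> TruthTable:
    payload = json.loads(Path(path).read_text())
    contigs = {
        cid: ContigTruth(
            contig_id=cid,
            segments=[Segment(**s) for s in d["segments"]],
            is_chimera=d["is_chimera"],
            breakpoints=list(d["breakpoints"]),
        )
        for cid, d in payload["contigs"].items()
    }
    return TruthTable(contigs=contigs, chrom_lengths=dict(payload["chrom_lengths"]))


# ---------------------------------------------------------------------------
# Recovery scoring


def evaluate_recovery(
    truth: TruthTable,
    layout: ScaffoldLayout,
    breakpoints: Sequence[Breakpoint] = (),
    name_map: Mapping[str, list[tuple[str, int, int]]] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
    tolerance: int | None = None,
) -> dict:
    """Score a scaffold layout against the simulator's ground truth.

    Reports per-chromosome Kendall tau of contig order, orientation accuracy,
    chimera breakpoint precision/recall (a call within ``tolerance`` bp of a
    true join — default one intergenic spacer — counts), adjacent-true-pair
    order accuracy, and the placement rate when lengths are supplied.
    Conventions: a chromosome with fewer than two recovered units scores tau
    1.0; with no true and no called breakpoints precision and recall are 1.0.
    """
    tol = 2000 if tolerance is None else tolerance

    # current name of each truth segment (identity unless the contig was split)
    def segment_unit(cid: str, seg: Segment) -> str:
        if name_map is None or cid not in name_map or len(name_map[cid]) == 1:
            return cid
        best, best_ov = cid, -1
        for new, s, e in name_map[cid]:
            ov = min(e, seg.contig_end) - max(s, seg.contig_start)
            if ov > best_ov:
                best, best_ov = new, ov
        return best

    true_units: dict[str, list[tuple[int, str, str]]] = {}  # chrom -> (order, unit, ori)
    for cid, t in truth.contigs.items():
        for seg in t.segments:
            true_units.setdefault(seg.chromosome, []).append(
                (seg.order_index, segment_unit(cid, seg), seg.orientation)
            )
    for units in true_units.values():
        units.sort()

    pos_in_group: dict[str, dict[str, int]] = {}
    ori_in_group: dict[str, dict[str, str]] = {}
    for grp, placements in layout.groups.items():
        pos_in_group[grp] = {cid: i for i, (cid, _) in enumerate(placements)}
        ori_in_group[grp] = {cid: o for cid, o in placements}

    taus: dict[str, float] = {}
    ori_total = ori_correct = 0
    adj_total = adj_correct = 0
    for chrom, units in true_units.items():
        recovered = [
            (order, pos_in_group.get(chrom, {}).get(unit))
            for order, unit, _ in units
        ]
        present = [(o, p) for o, p in recovered if p is not None]
        if len(present) < 2:
            taus[chrom] = 1.0
        else:
            tau, _ = kendalltau([o for o, _ in present], [p for _, p in present])
            taus[chrom] = round(float(tau), 10)  # shed float noise at +/-1
        for order, unit, true_ori in units:
            got = ori_in_group.get(chrom, {}).get(unit)
            if got is not None:
                ori_total += 1
                ori_correct += got == true_ori
        placed = {o: p for o, p in present}
        for (o1, _, _), (o2, _, _) in zip(units, units[1:]):
            if o1 in placed and o2 in placed:
                adj_total += 1
                adj_correct += placed[o1] < placed[o2]

    true_bps = truth.true_breakpoints()
    called = [(b.contig_id, b.position) for b in breakpoints]
    matched_true = sum(
        1
        for cid, pos in true_bps
        if any(c == cid and abs(p - pos) <= tol for c, p in called)
    )
    matched_called = sum(
        1
        for c, p in called
        if any(cid == c and abs(p - pos) <= tol for cid, pos in true_bps)
    )
    recall = matched_true / len(true_bps) if true_bps else 1.0
    precision = matched_called / len(called) if called else 1.0

    metrics = {
        "tau_per_chromosome": taus,
        "mean_tau": float(np.mean(list(taus.values()))) if taus else 1.0,
        "orientation_accuracy": ori_correct / ori_total if ori_total else 1.0,
        "adjacent_pair_accuracy": adj_correct / adj_total if adj_total else 1.0,
        "chimera_precision": precision,
        "chimera_recall": recall,
        "n_true_breakpoints": len(true_bps),
        "n_called_breakpoints": len(called),
    }
    if contig_lengths is not None:
        total = sum(contig_lengths.values())
        placed_bp = sum(contig_lengths[c] for c in layout.placed_contigs())
        metrics["placement_rate"] = round(100.0 * placed_bp / total, 2)
    return metrics
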