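"""Haplotype-variation analysis between a primary assembly and its haplotigs.

Two disjoint regimes: small variants (REF and ALT both <= 10 bp, from a
VCF-like table) are binned against genomic feature classes; larger
differences are inferred from the signed reference/query gaps between
consecutive alignment blocks and classified into six structural classes
(the between-alignment logic popularized by Assemblytics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

__all__ = [
    "AlignmentBlock",
    "SmallVariant",
    "LargeVariant",
    "VARIANT_CLASSES",
    "read_small_variants",
    "read_alignment_blocks",
    "upstream_intervals",
    "small_variant_density",
    "classify_large_variant",
    "variants_from_blocks",
    "summarize_variants",
    "write_variant_bed",
]

VARIANT_CLASSES = (
    "insertion",
    "deletion",
    "repeat_expansion",
    "repeat_contraction",
    "tandem_expansion",
    "tandem_contraction",
)

SWAPPED_CLASS = {
    "insertion": "deletion",
    "deletion": "insertion",
    "repeat_expansion": "repeat_contraction",
    "repeat_contraction": "repeat_expansion",
    "tandem_expansion": "tandem_contraction",
    "tandem_contraction": "tandem_expansion",
}


@dataclass(frozen=True)
class AlignmentBlock:
    """One whole-genome-alignment block (0-based half-open on both sides)."""

    ref_id: str
    ref_start: int
    ref_end: int
    query_id: str
    query_start: int
    query_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.ref_start < self.ref_end:
            raise ValueError("ref_start must be < ref_end")
        if not self.query_start < self.query_end:
            raise ValueError("query_start must be < query_end")


@dataclass(frozen=True)
class SmallVariant:
    ref_id: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")


@dataclass(frozen=True)
class LargeVariant:
    ref_id: str
    pos: int
    ref_gap: int  # signed R
    query_gap: int  # signed Q
    size: int
    variant_class: str


def read_small_variants(path: str | Path) -> list[SmallVariant]:
    """Read CHROM/POS/REF/ALT from a (plain-text) VCF; one record per ALT."""
    out: list[SmallVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                out.append(SmallVariant(rec.chrom, rec.pos - 1, rec.ref, alt))
    return out


def read_alignment_blocks(path: str | Path) -> list[AlignmentBlock]:
    """Read a coords-style TSV: ref_id ref_start ref_end query_id query_start query_end strand."""
    df = pd.read_csv(path, sep="\t")
    return [
        AlignmentBlock(
            str(r.ref_id),
            int(r.ref_start),
            int(r.ref_end),
            str(r.query_id),
            int(r.query_start),
            int(r.query_end),
            str(getattr(r, "strand", "+")),
        )
        for r in df.itertuples(index=False)
    ]


def upstream_intervals(
    loci: Iterable[tuple[str, int, int, str]],
    chrom_lengths: Mapping[str, int],
    flank: int = 1000,
) -> list[tuple[str, int, int]]:
    """The ``flank`` bp 5' of each locus, strand-aware, clipped at chromosome edges."""
    out = []
    for chrom, start, end, strand in loci:
        if chrom not in chrom_lengths:
            raise KeyError(f"locus on unknown chromosome {chrom}")
        if strand == "+":
            s, e = max(0, start - flank), start
        else:
            s, e = end, min(chrom_lengths[chrom], end + flank)
        if e > s:
            out.append((chrom, s, e))
    return out


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def small_variant_density(
    variants: Iterable[SmallVariant],
    features: Iterable[tuple[str, int, int, str]],
    chrom_lengths: Mapping[str, int],
    bin_size: int = 1_000_000,
    max_allele_len: int = 10,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-bin, per-feature-class small-variant densities (variants per kb).

    Variants whose REF or ALT exceeds ``max_allele_len`` bp are excluded
    first.  For each (chromosome bin, feature class) the density is the count
    of retained variants falling inside that class's (merged) intervals
    within the bin, divided by the class bp in the bin / 1000.  Bins with
    zero feature bp are omitted from the per-class median.
    """
    kept = [
        v
        for v in variants
        if len(v.ref_allele) <= max_allele_len and len(v.alt_allele) <= max_allele_len
    ]
    by_class_chrom: dict[tuple[str, str], list[tuple[int, int]]] = {}
    classes: set[str] = set()
    for chrom, start, end, label in features:
        if chrom not in chrom_lengths:
            raise KeyError(f"feature on unknown chromosome {chrom}")
        by_class_chrom.setdefault((label, chrom), []).append((start, end))
        classes.add(label)

    trees: dict[tuple[str, str], IntervalTree] = {}
    merged: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for key, ivs in by_class_chrom.items():
        m = _merge(ivs)
        merged[key] = m
        trees[key] = IntervalTree.from_tuples(m)

    var_by_chrom: dict[str, list[SmallVariant]] = {}
    for v in kept:
        var_by_chrom.setdefault(v.ref_id, []).append(v)

    rows = []
    for chrom, length in chrom_lengths.items():
        bins = [(s, min(s + bin_size, length)) for s in range(0, length, bin_size)]
        for label in sorted(classes):
            key = (label, chrom)
            ivs = merged.get(key, [])
            tree = trees.get(key)
            for bs, be in bins:
                feature_bp = sum(
                    max(0, min(e, be) - max(s, bs)) for s, e in ivs
                )
                if feature_bp == 0:
                    nvar = 0
                    density = float("nan")
                else:
                    nvar = sum(
                        1
                        for v in var_by_chrom.get(chrom, [])
                        if bs <= v.pos < be and tree is not None and tree.overlaps_point(v.pos)
                    )
                    density = nvar / (feature_bp / 1000.0)
                rows.append((chrom, bs, be, label, feature_bp, nvar, density))
    df = pd.DataFrame(
        rows,
        columns=["chromosome", "bin_start", "bin_end", "feature", "feature_bp", "n_variants", "density"],
    )
    medians = df[df.feature_bp > 0].groupby("feature")["density"].median()
    return df, medians


def classify_large_variant(
    ref_gap: int,
    query_gap: int,
    min_gap: int = 10,
    max_size: int = 10_000,
) -> tuple[str, int] | None:
    """Classify a between-alignment difference from its signed gaps.

    ``ref_gap`` (R) and ``query_gap`` (Q) are the signed distances between
    consecutive blocks on the reference and query; negative values are
    overlaps.  size = |Q - R|.  Q > R means extra query sequence
    (insertion side), Q < R extra reference sequence (deletion side); the
    sign pattern distinguishes plain indels (both gaps non-negative),
    repeat expansions/contractions (one side overlaps), and tandem
    expansions/contractions (both sides overlap).  Retained only when
    max(|R|, |Q|) > ``min_gap`` and size <= ``max_size``; Q == R is no
    variant. Returns (class, size) or None.
    """
    if query_gap == ref_gap:
        return None
    size = abs(query_gap - ref_gap)
    if max(abs(ref_gap), abs(query_gap)) <= min_gap or size > max_size:
        return None
    if query_gap > ref_gap:
        if ref_gap >= 0:
            cls = "insertion"
        elif query_gap >= 0:
            cls = "repeat_expansion"
        else:
            cls = "tandem_expansion"
    else:
        if query_gap >= 0:
            cls = "deletion"
        elif ref_gap >= 0:
            cls = "repeat_contraction"
        else:
            cls = "tandem_contraction"
    return cls, size


def variants_from_blocks(
    blocks: Iterable[AlignmentBlock],
    min_gap: int = 10,
    max_size: int = 10_000,
) -> list[LargeVariant]:
    """Between-block variants for each (query, ref, strand) pair of adjacent blocks.

    Blocks are grouped by (query_id, ref_id, strand) and walked in query
    order; for each adjacent pair, Q is the query gap and R the
    strand-oriented reference gap.
    """
    groups: dict[tuple[str, str, str], list[AlignmentBlock]] = {}
    for b in blocks:
        groups.setdefault((b.query_id, b.ref_id, b.strand), []).append(b)
    out: list[LargeVariant] = []
    for key in sorted(groups):
        blist = sorted(groups[key], key=lambda b: (b.query_start, b.query_end))
        for prev, nxt in zip(blist, blist[1:]):
            q_gap = nxt.query_start - prev.query_end
            if prev.strand == "+":
                r_gap = nxt.ref_start - prev.ref_end
                pos = prev.ref_end
            else:
                r_gap = prev.ref_start - nxt.ref_end
                pos = nxt.ref_end
            res = classify_large_variant(r_gap, q_gap, min_gap=min_gap, max_size=max_size)
            if res is not None:
                cls, size = res
                out.append(LargeVariant(prev.ref_id, pos, r_gap, q_gap, size, cls))
    return out


def summarize_variants(
    variants: Iterable[LargeVariant] | Mapping[str, int],
) -> dict[str, int]:
    """Six class counts plus their total, from variants or a counts mapping."""
    counts = {c: 0 for c in VARIANT_CLASSES}
    if isinstance(variants, Mapping):
        for cls, n in variants.items():
            if cls not in counts:
                raise KeyError(f"unknown variant class {cls!r}")
            counts[cls] += int(n)
    else:
        for v in variants:
            counts[v.variant_class] += 1
    counts["total"] = sum(counts[c] for c in VARIANT_CLASSES)
    return counts


def write_variant_bed(variants: Sequence[LargeVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#ref\tpos\tend\tclass\tsize\tref_gap\tquery_gap\n")
        for v in variants:
            fh.write(
                f"{v.ref_id}\t{v.pos}\t{v.pos + max(1, v.ref_gap)}\t"
                f"{v.variant_class}\t{v.size}\t{v.ref_gap}\t{v.query_gap}\n"
            )


def summary_json(variants: Sequence[LargeVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summarize_variants(variants), fh, indent=2, sort_keys=True)
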