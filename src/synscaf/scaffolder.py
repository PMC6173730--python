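"""Assign, order, and orient contigs into pseudomolecules.

The ordering procedure is a deterministic rank-consensus: within each linkage
group every map's positions are converted to normalized ranks in [0, 1] (cM
and bp are not commensurable, ranks are), each contig is scored by the
weighted mean rank of its anchors, and contigs are sorted by score.
Orientation is the sign of the weighted rank correlation between anchor
positions on the contig and their normalized map ranks.  Unlike a
genetic-algorithm path search, the result is a pure function of the input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .anchor_maps import AnchorPoint
from .formats_io import AgpRow, ScaffoldLayout, SeqRecord, layout_to_agp, revcomp

__all__ = [
    "PlacementStats",
    "assign_linkage_groups",
    "order_and_orient",
    "build_pseudomolecules",
    "assembly_stats",
    "n50",
    "percent",
    "write_placement_table",
]

DEFAULT_WEIGHTS = {"genetic": 1.0, "synteny": 1.0}


@dataclass(frozen=True)
class PlacementStats:
    total_bp: int
    anchored_bp: int
    placement_rate: float  # percent, 2 decimals
    n_contigs: int
    n_placed: int
    n50: int
    per_chromosome: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        d = self.__dict__.copy()
        return json.dumps(d, indent=2, sort_keys=True)


def percent(part: float, whole: float, digits: int = 2) -> float:
    """100 * part / whole, rounded to ``digits`` decimals."""
    if whole == 0:
        raise ZeroDivisionError("percent with zero denominator")
    return round(100.0 * part / whole, digits)


def n50(lengths: Iterable[int]) -> int:
    """Largest L such that pieces of length >= L cover half the total."""
    ls = sorted(lengths, reverse=True)
    if not ls:
        raise ValueError("n50 of an empty length set")
    half = sum(ls) / 2.0
    acc = 0
    for length in ls:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def assign_linkage_groups(
    anchors: Iterable[AnchorPoint],
    weights: Mapping[str, float] = DEFAULT_WEIGHTS,
) -> dict[str, str]:
    """Assign each anchored contig to its strict-majority linkage group.

    The vote for a group is the sum of map-weight x anchor-weight over the
    contig's anchors in that group; an exact tie leaves the contig unplaced
    (absent from the result).
    """
    votes: dict[str, dict[str, float]] = {}
    for a in anchors:
        w = weights.get(a.map_name, 1.0) * a.weight
        votes.setdefault(a.contig_id, {}).setdefault(a.linkage_group, 0.0)
        votes[a.contig_id][a.linkage_group] += w
    assignment: dict[str, str] = {}
    for contig, counts in votes.items():
        top = max(counts.values())
        winners = [g for g, v in counts.items() if v == top]
        if len(winners) == 1:
            assignment[contig] = winners[0]
    return assignment


def _normalized_ranks(values: np.ndarray) -> np.ndarray:
    """Average ranks rescaled to [0, 1]; a single value maps to 0.5."""
    n = len(values)
    if n == 1:
        return np.array([0.5])
    r = rankdata(values, method="average")
    return (r - 1.0) / (n - 1.0)


def _pair_preference(
    a_anchors: list[tuple[str, float, float]],
    b_anchors: list[tuple[str, float, float]],
) -> float:
    """Weighted vote for placing contig A before contig B.

    Sums w_a * w_b * sign(map_pos_b - map_pos_a) over anchor pairs of the
    same map (positions of different maps are never compared).  Positive
    means the maps put A before B.
    """
    pref = 0.0
    for map_a, pos_a, w_a in a_anchors:
        for map_b, pos_b, w_b in b_anchors:
            if map_a != map_b:
                continue
            pref += w_a * w_b * float(np.sign(pos_b - pos_a))
    return pref


def _refine_order(
    order: list[str],
    contig_anchors: Mapping[str, list[tuple[str, float, float]]],
) -> list[str]:
    """Bounded bubble passes swapping adjacent contigs the maps disagree with.

    The mean-rank score can invert neighbours when a sparse map's rank
    quantiles disagree with a dense map's; the pairwise anchor vote is
    unambiguous whenever every anchor of one contig precedes every anchor of
    the other, so noise-free data always sorts exactly.  Swaps happen only on
    a strictly negative preference, so score ties keep their tie-break order.
    """
    order = list(order)
    for _ in range(len(order)):
        swapped = False
        for i in range(len(order) - 1):
            a, b = order[i], order[i + 1]
            if _pair_preference(contig_anchors[a], contig_anchors[b]) < 0:
                order[i], order[i + 1] = b, a
                swapped = True
        if not swapped:
            break
    return order


def _group_by(items: Iterable, key) -> dict:
    out: dict = {}
    for it in items:
        out.setdefault(key(it), []).append(it)
    return out


def _weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    cov = (w * (x - mx) * (y - my)).sum()
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(cov / np.sqrt(vx * vy))


def order_and_orient(
    anchors: Iterable[AnchorPoint],
    assignment: Mapping[str, str],
    contig_lengths: Mapping[str, int],
    weights: Mapping[str, float] = DEFAULT_WEIGHTS,
    within_gap: int = 100,
    unplaced_gap: int = 1000,
) -> ScaffoldLayout:
    """Order and orient assigned contigs; pool everything else as unplaced.

    Only anchors agreeing with the contig's assigned group contribute.  Ties
    in the position score go to the longer contig, then the smaller id.  A
    contig whose anchors carry no orientation signal (single anchor, or zero
    rank correlation) is oriented "+" by convention.  Unplaced contigs are
    pooled by descending length (then id).
    """
    anchors = list(anchors)
    by_group: dict[str, list[AnchorPoint]] = {}
    for a in anchors:
        grp = assignment.get(a.contig_id)
        if grp is not None and a.linkage_group == grp:
            by_group.setdefault(grp, []).append(a)

    layout = ScaffoldLayout(within_gap=within_gap, unplaced_gap=unplaced_gap)
    scores: dict[str, dict[str, float]] = {}
    for grp in sorted(by_group):
        grp_anchors = by_group[grp]
        # per-map normalized ranks within the group
        norm: list[float] = [0.0] * len(grp_anchors)
        by_map: dict[str, list[int]] = {}
        for i, a in enumerate(grp_anchors):
            by_map.setdefault(a.map_name, []).append(i)
        for idxs in by_map.values():
            vals = np.array([grp_anchors[i].map_pos for i in idxs], dtype=float)
            for i, r in zip(idxs, _normalized_ranks(vals)):
                norm[i] = float(r)

        per_contig: dict[str, list[int]] = {}
        for i, a in enumerate(grp_anchors):
            per_contig.setdefault(a.contig_id, []).append(i)

        placements: list[tuple[float, int, str, str]] = []
        grp_scores: dict[str, float] = {}
        for contig, idxs in per_contig.items():
            w = np.array(
                [weights.get(grp_anchors[i].map_name, 1.0) * grp_anchors[i].weight for i in idxs]
            )
            r = np.array([norm[i] for i in idxs])
            p = np.array([grp_anchors[i].contig_pos for i in idxs], dtype=float)
            score = float((w * r).sum() / w.sum())
            grp_scores[contig] = score
            # orientation: rank correlation computed within each map (ranks of
            # different maps are not comparable), combined by total map weight
            vote = 0.0
            for map_name, sub in _group_by(
                idxs, key=lambda i: grp_anchors[i].map_name
            ).items():
                if len(sub) < 2:
                    continue
                pp = np.array([grp_anchors[i].contig_pos for i in sub], dtype=float)
                mm = np.array([grp_anchors[i].map_pos for i in sub], dtype=float)
                ww = np.array(
                    [weights.get(map_name, 1.0) * grp_anchors[i].weight for i in sub]
                )
                vote += ww.sum() * _weighted_corr(rankdata(pp), rankdata(mm), ww)
            ori = "-" if vote < 0 else "+"
            placements.append((score, -contig_lengths.get(contig, 0), contig, ori))
        placements.sort(key=lambda t: (t[0], t[1], t[2]))
        oris = {contig: ori for _, _, contig, ori in placements}
        contig_anchors = {
            contig: [
                (
                    grp_anchors[i].map_name,
                    grp_anchors[i].map_pos,
                    weights.get(grp_anchors[i].map_name, 1.0) * grp_anchors[i].weight,
                )
                for i in idxs
            ]
            for contig, idxs in per_contig.items()
        }
        ordered = _refine_order([c for _, _, c, _ in placements], contig_anchors)
        layout.groups[grp] = [(contig, oris[contig]) for contig in ordered]
        scores[grp] = grp_scores

    placed = set(layout.placed_contigs())
    pool = [c for c in contig_lengths if c not in placed]
    pool.sort(key=lambda c: (-contig_lengths[c], c))
    layout.unplaced = pool
    layout.scores = scores  # type: ignore[attr-defined]  # diagnostic side table
    return layout


def build_pseudomolecules(
    layout: ScaffoldLayout,
    contigs: Sequence[SeqRecord],
) -> tuple[list[SeqRecord], list[AgpRow]]:
    """Emit one sequence per linkage group plus one pooled unplaced sequence.

    Placed contigs are concatenated in layout order ("-" reverse-complemented)
    with ``within_gap`` Ns between neighbours; unplaced contigs are merged
    into a single sequence separated by ``unplaced_gap`` Ns.
    """
    seqs = {c.id: c.sequence for c in contigs}
    for cid in layout.placed_contigs() + list(layout.unplaced):
        if cid not in seqs:
            raise KeyError(f"layout contig {cid} missing from sequence set")

    records: list[SeqRecord] = []
    for grp in sorted(layout.groups):
        parts = []
        for cid, ori in layout.groups[grp]:
            parts.append(revcomp(seqs[cid]) if ori == "-" else seqs[cid])
        records.append(SeqRecord(grp, ("N" * layout.within_gap).join(parts)))
    if layout.unplaced:
        parts = [seqs[cid] for cid in layout.unplaced]
        records.append(
            SeqRecord(layout.unplaced_name, ("N" * layout.unplaced_gap).join(parts))
        )
    agp_rows = layout_to_agp(layout, {cid: len(s) for cid, s in seqs.items()})
    return records, agp_rows


def assembly_stats(contigs: Sequence[SeqRecord], layout: ScaffoldLayout) -> PlacementStats:
    """Placement statistics: totals, rate (2 decimals), contig N50, per-group sizes."""
    if not contigs:
        raise ValueError("no contigs")
    lengths = {c.id: len(c) for c in contigs}
    total = sum(lengths.values())
    placed_ids = layout.placed_contigs()
    anchored = sum(lengths[c] for c in placed_ids)
    per_chrom = {}
    for grp, placements in layout.groups.items():
        k = len(placements)
        per_chrom[grp] = sum(lengths[c] for c, _ in placements) + max(0, k - 1) * layout.within_gap
    return PlacementStats(
        total_bp=total,
        anchored_bp=anchored,
        placement_rate=percent(anchored, total, 2),
        n_contigs=len(contigs),
        n_placed=len(placed_ids),
        n50=n50(lengths.values()),
        per_chromosome=per_chrom,
    )


def write_placement_table(layout: ScaffoldLayout, path: str | Path) -> None:
    scores = getattr(layout, "scores", {})
    with open(path, "w") as fh:
        fh.write("contig\tgroup\tposition_score\torientation\n")
        for grp in sorted(layout.groups):
            for cid, ori in layout.groups[grp]:
                s = scores.get(grp, {}).get(cid, float("nan"))
                fh.write(f"{cid}\t{grp}\t{s:.6f}\t{ori}\n")
        for cid in layout.unplaced:
            fh.write(f"{cid}\tunplaced\tnan\t+\n")
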