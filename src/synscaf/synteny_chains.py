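"""Collinear gene-pair chains in rank space, with per-pair Ks (NG86).

Matches between two gene sets are chained by a dynamic program over gene
ranks (the DAGChainer idea): a chain is a strictly increasing sequence of
matches in both rank axes with per-axis gaps at most D, scored as the sum of
match scores minus a linear gap penalty.  Chains shorter than A pairs are
discarded; inverted chains are found by negating one rank axis.  Synonymous
substitution rates per pair use the Nei–Gojobori (1986) proportion estimator
with the Jukes–Cantor correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "Match",
    "ChainParams",
    "SyntenyChain",
    "match_score",
    "matches_from_hits",
    "chain_matches",
    "KsResult",
    "ks_ng86",
    "attach_ks",
    "chain_summary",
    "dotplot",
]


@dataclass(frozen=True)
class Match:
    """One cross-genome gene pair located by its ranks on the two genomes."""

    x_rank: int
    y_rank: int
    x_gene: str
    y_gene: str
    score: float

    def __post_init__(self) -> None:
        if self.x_rank < 1 or self.y_rank < 1:
            raise ValueError("ranks must be >= 1")
        if self.score <= 0:
            raise ValueError("match score must be > 0")


@dataclass(frozen=True)
class ChainParams:
    max_gap: int = 20  # D: max rank gap on either axis
    min_pairs: int = 5  # A: minimum chain length
    gap_penalty: float = 1.0  # lambda, per skipped rank

    def __post_init__(self) -> None:
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")
        if self.min_pairs < 2:
            raise ValueError("min_pairs must be >= 2")
        if self.gap_penalty < 0:
            raise ValueError("gap_penalty must be >= 0")


@dataclass
class SyntenyChain:
    matches: list[Match]
    score: float
    orientation: str  # "forward" | "inverted"
    ks: list[float | None] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.matches)

    @property
    def median_ks(self) -> float | None:
        vals = sorted(k for k in self.ks if k is not None)
        if not vals:
            return None
        m = len(vals)
        mid = m // 2
        return vals[mid] if m % 2 else (vals[mid - 1] + vals[mid]) / 2.0


def match_score(evalue: float) -> float:
    """min(50, -log10 evalue); an evalue of 0 is capped at 50."""
    if evalue <= 0:
        return 50.0
    return min(50.0, -math.log10(evalue))


def matches_from_hits(
    hits: Iterable,
    x_ranks: Mapping[str, tuple[int, str]],
    y_ranks: Mapping[str, tuple[int, str]],
) -> list[Match]:
    """Build deduplicated matches from a cross-genome hit table.

    ``x_ranks``/``y_ranks`` map gene (or isoform) ids to (rank, gene_id);
    per (x_gene, y_gene) pair the best-scoring hit is kept.
    """
    best: dict[tuple[str, str], Match] = {}
    for h in hits:
        if h.query_id not in x_ranks or h.subject_id not in y_ranks:
            continue
        xr, xg = x_ranks[h.query_id]
        yr, yg = y_ranks[h.subject_id]
        m = Match(xr, yr, xg, yg, match_score(h.evalue))
        key = (xg, yg)
        if key not in best or m.score > best[key].score:
            best[key] = m
    return sorted(best.values(), key=lambda m: (m.x_rank, m.y_rank))


def _best_chain(
    pts: Sequence[Match],
    params: ChainParams,
    inverted: bool,
) -> tuple[list[int], float] | None:
    """Exact best chain with >= min_pairs matches (indices into pts), or None.

    DP over matches sorted by (x, y) with a bounded length dimension:
    f[i][l] is the best score of a chain ending at i whose length, capped at
    A = min_pairs, is l.  The l = A layer absorbs all longer chains, so
    max_i f[i][A] is the optimum among chains satisfying the length floor.
    """
    A = params.min_pairs
    D = params.max_gap
    lam = params.gap_penalty
    sign = -1 if inverted else 1
    order = sorted(range(len(pts)), key=lambda i: (pts[i].x_rank, sign * pts[i].y_rank))
    xs = [pts[i].x_rank for i in order]
    ys = [sign * pts[i].y_rank for i in order]
    sc = [pts[i].score for i in order]
    n = len(order)
    NEG = float("-inf")
    f = [[NEG] * (A + 1) for _ in range(n)]
    parent: list[list[tuple[int, int] | None]] = [[None] * (A + 1) for _ in range(n)]
    for i in range(n):
        f[i][1] = sc[i]
        j = i - 1
        while j >= 0 and xs[i] - xs[j] <= D:
            dx = xs[i] - xs[j]
            dy = ys[i] - ys[j]
            if 0 < dx and 0 < dy <= D:
                gap = lam * ((dx - 1) + (dy - 1))
                for l_prev in range(1, A + 1):
                    if f[j][l_prev] == NEG:
                        continue
                    l_new = min(A, l_prev + 1)
                    cand = sc[i] + f[j][l_prev] - gap
                    if cand > f[i][l_new]:
                        f[i][l_new] = cand
                        parent[i][l_new] = (j, l_prev)
            j -= 1
    best_i, best_score = -1, NEG
    for i in range(n):
        if f[i][A] > best_score:
            best_i, best_score = i, f[i][A]
    if best_i < 0:
        return None
    idxs: list[int] = []
    i, l = best_i, A
    while i is not None:
        idxs.append(order[i])
        nxt = parent[i][l]
        if nxt is None:
            break
        i, l = nxt
    idxs.reverse()
    return idxs, best_score


def chain_matches(
    matches: Sequence[Match], params: ChainParams = ChainParams()
) -> list[SyntenyChain]:
    """Extract non-overlapping chains greedily by descending chain score.

    At each step the best remaining forward chain and the best remaining
    inverted chain (y ranks negated) are computed exactly; the higher-scoring
    one is emitted and its matches retired (forward wins ties).  Stops when
    no chain of at least ``min_pairs`` matches remains.
    """
    remaining = list(matches)
    chains: list[SyntenyChain] = []
    while remaining:
        fwd = _best_chain(remaining, params, inverted=False)
        inv = _best_chain(remaining, params, inverted=True)
        if fwd is None and inv is None:
            break
        if inv is None or (fwd is not None and fwd[1] >= inv[1]):
            idxs, score = fwd
            orientation = "forward"
        else:
            idxs, score = inv
            orientation = "inverted"
        chosen = [remaining[i] for i in idxs]
        chains.append(SyntenyChain(chosen, score, orientation))
        used = set(idxs)
        remaining = [m for i, m in enumerate(remaining) if i not in used]
    return chains


# ---------------------------------------------------------------------------
# NG86 synonymous substitution rate

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_CODON_TABLE.stop_codons)
_BASES = "ACGT"


def _aa(codon: str) -> str | None:
    """Amino acid, or None for a stop codon."""
    if codon in _STOPS:
        return None
    return _CODON_TABLE.forward_table[codon]


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Synonymous sites of a codon: per position, the fraction of the three
    single-base substitutions that preserve the amino acid (changes to stop
    codons count as nonsynonymous)."""
    aa0 = _aa(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if _aa(mut) is not None and _aa(mut) == aa0:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def _syn_diffs(c1: str, c2: str) -> float:
    """Synonymous differences between two codons, averaged over all
    substitution orderings (paths through stop codons are traversed but a
    step producing or leaving a stop codon is nonsynonymous)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0
    total = 0.0
    n_paths = 0
    for path in permutations(diff_pos):
        cur = c1
        sd = 0.0
        for pos in path:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            a1, a2 = _aa(cur), _aa(nxt)
            if a1 is not None and a2 is not None and a1 == a2:
                sd += 1.0
            cur = nxt
        total += sd
        n_paths += 1
    return total / n_paths


@dataclass(frozen=True)
class KsResult:
    ks: float | None
    S: float = 0.0
    Sd: float = 0.0
    pS: float = 0.0
    status: str = "ok"  # ok | saturated | skipped
    reason: str = ""


def ks_ng86(cds1: str, cds2: str) -> KsResult:
    """Ks between two pre-aligned, equal-length CDS (NG86 + Jukes–Cantor).

    Pairs with mismatched lengths, lengths not divisible by three, or
    internal stop codons are skipped (status "skipped"); pS >= 3/4 cannot be
    corrected and is flagged "saturated".  A shared trailing stop codon is
    ignored.
    """
    s1, s2 = cds1.upper(), cds2.upper()
    if len(s1) != len(s2):
        return KsResult(None, status="skipped", reason="length mismatch")
    if len(s1) == 0 or len(s1) % 3:
        return KsResult(None, status="skipped", reason="length not divisible by 3")
    if set(s1 + s2) - set(_BASES):
        return KsResult(None, status="skipped", reason="non-ACGT characters")
    codons = [(s1[i : i + 3], s2[i : i + 3]) for i in range(0, len(s1), 3)]
    if codons and codons[-1][0] in _STOPS and codons[-1][1] in _STOPS:
        codons = codons[:-1]
    if not codons:
        return KsResult(None, status="skipped", reason="no codons")
    for c1, c2 in codons:
        if c1 in _STOPS or c2 in _STOPS:
            return KsResult(None, status="skipped", reason="internal stop codon")
    S1 = sum(_syn_sites(c1) for c1, _ in codons)
    S2 = sum(_syn_sites(c2) for _, c2 in codons)
    S = (S1 + S2) / 2.0
    Sd = sum(_syn_diffs(c1, c2) for c1, c2 in codons)
    if S == 0:
        return KsResult(None, S=S, Sd=Sd, status="skipped", reason="no synonymous sites")
    pS = Sd / S
    if pS >= 0.75:
        return KsResult(None, S=S, Sd=Sd, pS=pS, status="saturated")
    ks = -0.75 * math.log(1.0 - (4.0 / 3.0) * pS)
    return KsResult(ks, S=S, Sd=Sd, pS=pS, status="ok")


def attach_ks(
    chains: Iterable[SyntenyChain],
    cds_x: Mapping[str, str],
    cds_y: Mapping[str, str],
) -> None:
    """Compute per-pair Ks for every chain in place (None where not computable)."""
    for chain in chains:
        chain.ks = []
        for m in chain.matches:
            a = cds_x.get(m.x_gene)
            b = cds_y.get(m.y_gene)
            if a is None or b is None:
                chain.ks.append(None)
                continue
            res = ks_ng86(a, b)
            chain.ks.append(res.ks)


def chain_summary(
    chains: Sequence[SyntenyChain],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chain table and a dotplot-ready pair-level table."""
    chain_rows = []
    pair_rows = []
    for cid, chain in enumerate(chains, start=1):
        ks = chain.ks if chain.ks else [None] * len(chain)
        chain_rows.append(
            (cid, len(chain), chain.orientation, chain.score, chain.median_ks)
        )
        for m, k in zip(chain.matches, ks):
            pair_rows.append((cid, m.x_rank, m.y_rank, m.x_gene, m.y_gene, k))
    chains_df = pd.DataFrame(
        chain_rows, columns=["chain_id", "n_pairs", "orientation", "score", "median_ks"]
    )
    pairs_df = pd.DataFrame(
        pair_rows, columns=["chain_id", "x_rank", "y_rank", "x_gene", "y_gene", "ks"]
    )
    return chains_df, pairs_df


def dotplot(pairs_df: pd.DataFrame, path: str | Path, max_ks: float = 5.0) -> None:
    """Rank-space dotplot colored by Ks (saturated/missing pairs in grey)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    have = pairs_df[pairs_df.ks.notna()]
    miss = pairs_df[pairs_df.ks.isna()]
    if len(miss):
        ax.scatter(miss.x_rank, miss.y_rank, s=6, c="lightgrey", label="no Ks")
    if len(have):
        sc = ax.scatter(
            have.x_rank,
            have.y_rank,
            s=6,
            c=have.ks.clip(upper=max_ks),
            cmap="viridis",
        )
        fig.colorbar(sc, ax=ax, label="Ks")
    ax.set_xlabel("gene rank, genome x")
    ax.set_ylabel("gene rank, genome y")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
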