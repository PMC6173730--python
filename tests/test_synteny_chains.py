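import itertools
import math

import numpy as np
import pytest

from synscaf.synteny_chains import (
    ChainParams,
    Match,
    SyntenyChain,
    chain_matches,
    chain_summary,
    ks_ng86,
    match_score,
)


def diagonal(n, start=1, score=10.0, y_offset=0):
    return [
        Match(start + i, start + i + y_offset, f"x{start + i}", f"y{start + i}", score)
        for i in range(n)
    ]


def exhaustive_best_chain(matches, params, inverted=False):
    """Independent oracle: enumerate every valid chain of >= min_pairs matches."""
    sign = -1 if inverted else 1
    pts = [(m.x_rank, sign * m.y_rank, m.score) for m in matches]

    best = [None]

    def rec(last_idx, length, score):
        if length >= params.min_pairs and (best[0] is None or score > best[0]):
            best[0] = score
        for i in range(last_idx + 1, len(pts)):
            dx = pts[i][0] - pts[last_idx][0]
            dy = pts[i][1] - pts[last_idx][1]
            if 0 < dx <= params.max_gap and 0 < dy <= params.max_gap:
                gap = params.gap_penalty * ((dx - 1) + (dy - 1))
                rec(i, length + 1, score + pts[i][2] - gap)

    order = sorted(range(len(pts)), key=lambda i: (pts[i][0], pts[i][1]))
    pts = [pts[i] for i in order]
    for i in range(len(pts)):
        rec(i, 1, pts[i][2])
    return best[0]


class TestChainMatches:
    def test_perfect_diagonal_single_chain(self):
        chains = chain_matches(diagonal(5))
        assert len(chains) == 1
        assert len(chains[0]) == 5
        assert chains[0].score == pytest.approx(50.0)
        assert chains[0].orientation == "forward"

    def test_four_matches_below_min_pairs(self):
        assert chain_matches(diagonal(4)) == []

    def test_large_gap_splits_chains(self):
        matches = diagonal(5) + diagonal(5, start=27)  # 21-rank gap > D=20
        chains = chain_matches(matches)
        assert sorted(len(c) for c in chains) == [5, 5]

    def test_gap_within_d_bridged_with_penalty(self):
        matches = diagonal(5) + diagonal(5, start=16)  # gap of 10 <= D
        (chain,) = chain_matches(matches)
        assert len(chain) == 10
        assert chain.score == pytest.approx(100.0 - 2 * 10.0)

    def test_inverted_chain_detected(self):
        matches = [Match(i, 100 - i, f"x{i}", f"y{i}", 10.0) for i in range(1, 7)]
        (chain,) = chain_matches(matches)
        assert chain.orientation == "inverted"
        assert len(chain) == 6

    def test_matches_used_at_most_once(self):
        matches = diagonal(10)
        chains = chain_matches(matches, ChainParams(min_pairs=3))
        seen = [m for c in chains for m in c.matches]
        assert len(seen) == len(set((m.x_rank, m.y_rank) for m in seen))

    @pytest.mark.parametrize("trial", range(30))
    def test_best_chain_equals_exhaustive_search(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 13))
        params = ChainParams(
            max_gap=int(rng.integers(2, 8)),
            min_pairs=int(rng.integers(2, 5)),
            gap_penalty=float(rng.choice([0.0, 0.5, 1.0, 2.0])),
        )
        xs = rng.choice(np.arange(1, 30), size=n, replace=False)
        ys = rng.choice(np.arange(1, 30), size=n, replace=False)
        matches = [
            Match(int(x), int(y), f"x{i}", f"y{i}", float(rng.integers(1, 20)))
            for i, (x, y) in enumerate(zip(xs, ys))
        ]
        oracle = max(
            (
                v
                for v in (
                    exhaustive_best_chain(matches, params, inverted=False),
                    exhaustive_best_chain(matches, params, inverted=True),
                )
                if v is not None
            ),
            default=None,
        )
        chains = chain_matches(matches, params)
        if oracle is None:
            assert chains == []
        else:
            assert chains[0].score == pytest.approx(oracle)

    def test_score_monotone_in_member_scores(self):
        matches = diagonal(6)
        base = chain_matches(matches)[0].score
        boosted = [
            Match(m.x_rank, m.y_rank, m.x_gene, m.y_gene, m.score + (5 if i == 2 else 0))
            for i, m in enumerate(matches)
        ]
        assert chain_matches(boosted)[0].score >= base


class TestMatchScore:
    def test_cap_and_log(self):
        assert match_score(0.0) == 50.0
        assert match_score(1e-100) == pytest.approx(50.0)
        assert match_score(1e-30) == pytest.approx(30.0)


def oracle_syn_sites(codon, translate):
    """Brute-force synonymous site count for one codon."""
    s = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if translate(mut) is not None and translate(mut) == translate(codon):
                s += 1 / 3
    return s


def oracle_syn_diffs(c1, c2, translate):
    """Brute-force pathway-averaged synonymous differences for a codon pair."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0
    totals = []
    for path in itertools.permutations(positions):
        cur, sd = c1, 0.0
        for pos in path:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if (
                translate(cur) is not None
                and translate(nxt) is not None
                and translate(cur) == translate(nxt)
            ):
                sd += 1
            cur = nxt
        totals.append(sd)
    return sum(totals) / len(totals)


def simple_translate(codon):
    from Bio.Data import CodonTable

    t = CodonTable.unambiguous_dna_by_id[1]
    return None if codon in t.stop_codons else t.forward_table[codon]


class TestKsNg86:
    def test_identical_sequences_zero(self):
        res = ks_ng86("ATGGCCATT", "ATGGCCATT")
        assert res.ks == 0.0 and res.status == "ok"

    def test_single_synonymous_difference_against_oracle(self):
        a, b = "TTTAAAGGGCCCGAA", "TTCAAAGGGCCCGAA"
        res = ks_ng86(a, b)
        S = sum(
            (oracle_syn_sites(a[i : i + 3], simple_translate)
             + oracle_syn_sites(b[i : i + 3], simple_translate)) / 2
            for i in range(0, len(a), 3)
        )
        Sd = sum(
            oracle_syn_diffs(a[i : i + 3], b[i : i + 3], simple_translate)
            for i in range(0, len(a), 3)
        )
        assert Sd == 1.0
        assert res.S == pytest.approx(S)
        assert res.Sd == pytest.approx(Sd)
        pS = Sd / S
        assert res.ks == pytest.approx(-0.75 * math.log(1 - 4 * pS / 3))

    def test_single_codon_saturates(self):
        res = ks_ng86("TTT", "TTC")
        assert res.status == "saturated"
        assert res.S == pytest.approx(1 / 3)
        assert res.pS == pytest.approx(3.0)

    def test_symmetry(self):
        a = "ATGGCTAGTTTACGAATC"
        b = "ATGGCAAGTCTACGTATC"
        assert ks_ng86(a, b).ks == pytest.approx(ks_ng86(b, a).ks)

    @pytest.mark.parametrize(
        "a,b,reason",
        [
            ("ATG", "ATGGCC", "length mismatch"),
            ("ATGC", "ATGC", "divisible"),
            ("ATGTAAGCC", "ATGTAAGCC", "stop"),
        ],
    )
    def test_degenerate_pairs_skipped_not_crashed(self, a, b, reason):
        res = ks_ng86(a, b)
        assert res.status == "skipped"
        assert reason.split()[0] in res.reason

    def test_fourfold_sites_match_jukes_cantor(self):
        # 3 third-position differences over 10 glycine codons: S = 10, pS = 0.3
        a = "GGA" * 10
        b = "GGG" * 3 + "GGA" * 7
        res = ks_ng86(a, b)
        assert res.S == pytest.approx(10.0)
        assert res.ks == pytest.approx(-0.75 * math.log(1 - 0.4))

    def test_random_pairs_match_brute_oracle(self):
        rng = np.random.default_rng(42)
        codons = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if simple_translate(a + b + c) is not None
        ]
        for _ in range(40):
            n = int(rng.integers(3, 12))
            s1 = "".join(rng.choice(codons, size=n))
            s2 = "".join(rng.choice(codons, size=n))
            res = ks_ng86(s1, s2)
            S = sum(
                (oracle_syn_sites(s1[i : i + 3], simple_translate)
                 + oracle_syn_sites(s2[i : i + 3], simple_translate)) / 2
                for i in range(0, 3 * n, 3)
            )
            Sd = sum(
                oracle_syn_diffs(s1[i : i + 3], s2[i : i + 3], simple_translate)
                for i in range(0, 3 * n, 3)
            )
            assert res.S == pytest.approx(S)
            assert res.Sd == pytest.approx(Sd)


class TestChainSummary:
    def chain(self, ks):
        matches = diagonal(len(ks))
        c = SyntenyChain(matches, 10.0 * len(ks), "forward")
        c.ks = ks
        return c

    def test_median_excludes_saturated(self):
        chains_df, _ = chain_summary([self.chain([0.03, 0.05, None])])
        assert chains_df.median_ks.iloc[0] == pytest.approx(0.04)

    def test_empty_and_all_saturated(self):
        chains_df, pairs_df = chain_summary([])
        assert chains_df.empty and pairs_df.empty
        chains_df, _ = chain_summary([self.chain([None, None, None, None, None])])
        assert chains_df.median_ks.iloc[0] is None or math.isnan(chains_df.median_ks.iloc[0])
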