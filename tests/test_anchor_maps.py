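import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synscaf.anchor_maps import (
    FilterParams,
    MarkerRecord,
    build_marker_anchors,
    build_synteny_anchors,
    filter_spurious_runs,
    rank_reference_genes,
    select_best_hits,
)
from synscaf.formats_io import GeneModel, TabularHit


def hit(query, subject, pos, *, strand="+", bitscore=500.0, aln=300, qs=0, qe=300):
    return TabularHit(
        query_id=query,
        subject_id=subject,
        pct_identity=98.0,
        aln_length=aln,
        query_start=qs,
        query_end=qe,
        subject_start=pos,
        subject_end=pos + aln,
        strand=strand,
        evalue=1e-50,
        bitscore=bitscore,
    )


def gene(gid, chrom="chr1", start=1000, stop=2000):
    return GeneModel(gid, f"{gid}.1", chrom, start, stop, "+")


class TestRankReferenceGenes:
    def test_rank_by_start(self):
        genes = [gene("g1", start=10, stop=11), gene("g2", start=5, stop=6), gene("g3", start=20, stop=21)]
        df = rank_reference_genes(genes)
        ranks = dict(zip(df.gene_id, df["rank"]))
        assert ranks == {"g2": 1, "g1": 2, "g3": 3}

    def test_tie_broken_by_gene_id(self):
        genes = [gene("gb", start=5, stop=6), gene("ga", start=5, stop=6)]
        df = rank_reference_genes(genes)
        assert list(df.gene_id) == ["ga", "gb"]

    def test_independent_numbering_per_chromosome(self):
        genes = [gene("a", "chr1"), gene("b", "chr2"), gene("c", "chr2", 5000, 6000)]
        df = rank_reference_genes(genes)
        assert set(df[df.chromosome == "chr2"]["rank"]) == {1, 2}
        assert list(df[df.chromosome == "chr1"]["rank"]) == [1]


class TestSelectBestHits:
    def test_max_bitscore_wins(self):
        best = select_best_hits([hit("g.1", "c1", 0, bitscore=500), hit("g.1", "c2", 0, bitscore=450)])
        assert best["g.1"].subject_id == "c1"

    def test_bitscore_tie_longer_alignment_wins(self):
        best = select_best_hits(
            [hit("g.1", "c1", 0, bitscore=500, aln=250), hit("g.1", "c2", 0, bitscore=500, aln=300)]
        )
        assert best["g.1"].subject_id == "c2"

    def test_full_tie_smaller_subject_id(self):
        best = select_best_hits([hit("g.1", "cB", 0), hit("g.1", "cA", 0)])
        assert best["g.1"].subject_id == "cA"

    def test_gene_without_hits_absent(self):
        assert "missing" not in select_best_hits([hit("g.1", "c1", 0)])


def labelled_contig(labels, contig="c1"):
    """One contig with hits whose queries map to the given chromosome labels."""
    hits = [hit(f"q{i}.1", contig, 1000 * i) for i in range(len(labels))]
    chrom_of = {f"q{i}.1": f"chr{lab}" for i, lab in enumerate(labels)}
    return hits, chrom_of


class TestFilterSpuriousRuns:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            ([1, 1, 5, 1, 1], [1, 1, 1, 1]),  # lone wrong-chromosome hit removed
            ([1, 5], [1, 5]),  # below min_hits_for_filter: untouched
            ([1, 5, 5, 1], [5, 5]),  # two isolated runs of chr1 removed
            ([1, 1, 1], [1, 1, 1]),
            ([1, 2, 3], []),  # all runs are singletons on a 3-hit contig
        ],
    )
    def test_run_removal(self, labels, expected):
        hits, chrom_of = labelled_contig(labels)
        kept = filter_spurious_runs(hits, chrom_of)
        assert [chrom_of[h.query_id] for h in kept] == [f"chr{x}" for x in expected]

    def test_single_pass_no_cascade(self):
        # after removing the 2-run, the two 1-runs of chr1 (lengths 2 and 2)
        # flank each other but are NOT re-merged and re-examined
        hits, chrom_of = labelled_contig([1, 1, 2, 1, 1])
        kept = filter_spurious_runs(hits, chrom_of, FilterParams(3, 2))
        assert [chrom_of[h.query_id] for h in kept] == []

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 4), min_size=0, max_size=20))
    def test_output_is_subsequence_and_small_contigs_untouched(self, labels):
        hits, chrom_of = labelled_contig(labels)
        kept = filter_spurious_runs(hits, chrom_of)
        ids = [h.query_id for h in hits]
        kept_ids = [h.query_id for h in kept]
        it = iter(ids)
        assert all(any(k == x for x in it) for k in kept_ids)  # subsequence
        if len(labels) < 3:
            assert kept_ids == ids


class TestBuildSyntenyAnchors:
    def genes(self):
        return [
            GeneModel(f"g{i}", f"g{i}.1", "chr1", 1000 * i, 1000 * i + 500, "+")
            for i in range(1, 5)
        ]

    def test_multi_hit_contig_one_anchor_per_hit(self):
        hits = [hit(f"g{i}.1", "c1", 2000 * i) for i in range(1, 4)]
        anchors = build_synteny_anchors(hits, self.genes())
        assert len(anchors) == 3
        assert all(a.map_name == "synteny" for a in anchors)
        # map_pos is the gene start
        assert sorted(a.map_pos for a in anchors) == [1000.0, 2000.0, 3000.0]

    def test_single_hit_contig_two_anchors(self):
        anchors = build_synteny_anchors([hit("g1.1", "c9", 100)], self.genes())
        assert len(anchors) == 2
        assert {a.map_pos for a in anchors} == {1000.0, 1500.0}  # gene start and stop
        # plus strand: start-side anchor is at the alignment start
        start_anchor = next(a for a in anchors if a.map_pos == 1000.0)
        assert start_anchor.contig_pos == 100

    def test_minus_strand_single_hit_inverts_contig_order(self):
        (a_start, a_stop) = build_synteny_anchors(
            [hit("g1.1", "c9", 100, strand="-")], self.genes()
        )
        assert a_start.map_pos == 1000.0 and a_stop.map_pos == 1500.0
        assert a_start.contig_pos > a_stop.contig_pos

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError):
            build_synteny_anchors([hit("ghost.1", "c1", 0)], self.genes())


class TestBuildMarkerAnchors:
    def marker(self, mid="m1"):
        return MarkerRecord(mid, "LG1", 12.5, flank_length=200, snp_offset=100)

    def test_plus_strand_snp_projection(self):
        # flank aligned in full at 0-based subject 999 (1-based 1000)
        h = hit("m1", "c1", 999, aln=200, qs=0, qe=200)
        anchors, report = build_marker_anchors([h], [self.marker()])
        assert report["placed"] == 1
        (a,) = anchors
        assert a.contig_pos == 1099
        assert (a.linkage_group, a.map_pos, a.map_name) == ("LG1", 12.5, "genetic")

    def test_minus_strand_snp_projection(self):
        h = hit("m1", "c1", 999, aln=200, qs=0, qe=200, strand="-")
        (a,), _ = build_marker_anchors([h], [self.marker()])
        assert a.contig_pos == 999 + 200 - 1 - 100

    def test_equal_score_placements_dropped(self):
        hits = [hit("m1", "c1", 0, aln=200, qe=200), hit("m1", "c2", 0, aln=200, qe=200)]
        anchors, report = build_marker_anchors(hits, [self.marker()])
        assert anchors == [] and report["ambiguous"] == 1

    def test_unaligned_marker_counted(self):
        anchors, report = build_marker_anchors([], [self.marker()])
        assert anchors == [] and report["unaligned"] == 1

    def test_offset_outside_alignment_dropped_not_raised(self):
        # only the first 50 bp of the flank aligned; SNP at offset 100 is outside
        h = hit("m1", "c1", 0, aln=50, qs=0, qe=50)
        anchors, report = build_marker_anchors([h], [self.marker()])
        assert anchors == [] and report["offset_outside"] == 1

    def test_low_identity_is_invisible(self):
        h = TabularHit("m1", "c1", 80.0, 200, 0, 200, 0, 200, "+", 1e-20, 100.0)
        anchors, report = build_marker_anchors([h], [self.marker()])
        assert report["unaligned"] == 1
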