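import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synscaf import formats_io
from synscaf.formats_io import (
    AgpRow,
    ScaffoldLayout,
    SeqRecord,
    agp_to_layout,
    layout_to_agp,
    parse_gene_models,
    parse_hits,
    parse_sequences,
    read_agp,
    reconstruct_from_agp,
    revcomp,
    write_agp,
    write_sequences,
)


class TestFasta:
    @pytest.mark.parametrize(
        "text,expected",
        [
            (">c1\nACGT", [("c1", "ACGT")]),
            (">c1\nAC\nGT\n>c2\nA", [("c1", "ACGT"), ("c2", "A")]),
            ("", []),
            (">c1\nacgtn", [("c1", "ACGTN")]),  # case folded
        ],
    )
    def test_parse(self, text, expected):
        records = parse_sequences(io.StringIO(text))
        assert [(r.id, r.sequence) for r in records] == expected

    def test_duplicate_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_sequences(io.StringIO(">a\nAC\n>a\nGT"))

    def test_empty_body_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            parse_sequences(io.StringIO(">a\n>b\nACGT"))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 10_000),
                st.text(alphabet="ACGTN", min_size=1, max_size=200),
            ),
            max_size=8,
            unique_by=lambda t: t[0],
        )
    )
    def test_round_trip_is_identity(self, tmp_path_factory, items):
        records = [SeqRecord(f"s{i}", seq) for i, seq in items]
        path = tmp_path_factory.mktemp("fa") / "rt.fa"
        write_sequences(records, path)
        back = parse_sequences(path)
        assert [(r.id, r.sequence) for r in back] == [
            (r.id, r.sequence) for r in records
        ]


class TestTabularHits:
    LINE = "q1\ts1\t98.5\t300\t3\t0\t1\t300\t5299\t5000\t1e-100\t500.5"

    def test_minus_strand_normalized(self):
        (hit,) = parse_hits(io.StringIO(self.LINE))
        assert hit.strand == "-"
        # (min, max) of the original subject coordinates preserved
        assert (hit.subject_start, hit.subject_end) == (4999, 5299)
        assert hit.bitscore == 500.5

    def test_plus_strand_and_offsets(self):
        line = "q1\ts1\t98.5\t300\t3\t0\t1\t300\t1000\t1299\t1e-100\t500"
        (hit,) = parse_hits(io.StringIO(line))
        assert hit.strand == "+"
        assert (hit.subject_start, hit.subject_end) == (999, 1299)
        assert (hit.query_start, hit.query_end) == (0, 300)

    def test_wrong_column_count_names_line(self):
        text = self.LINE + "\n" + "\t".join(self.LINE.split("\t")[:11])
        with pytest.raises(ValueError, match="line 2"):
            parse_hits(io.StringIO(text))

    def test_paf_dialect(self):
        line = "q1\t500\t10\t310\t-\tt1\t9000\t5000\t5300\t290\t300\t60"
        (hit,) = parse_hits(io.StringIO(line), dialect="paf")
        assert hit.strand == "-"
        assert (hit.subject_start, hit.subject_end) == (5000, 5300)
        assert hit.pct_identity == pytest.approx(100 * 290 / 300)

    def test_write_read_round_trip(self, tmp_path):
        hits = parse_hits(io.StringIO(self.LINE))
        path = tmp_path / "hits.tsv"
        formats_io.write_hits(hits, path)
        assert parse_hits(path) == hits


GFF = """##gff-version 3
chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=g1.1;Parent=g1
chr1\tsrc\tmRNA\t101\t190\t.\t+\t.\tID=g1.2;Parent=g1
chr2\tsrc\tgene\t51\t150\t.\t-\t.\tID=g2
chr2\tsrc\tmRNA\t51\t150\t.\t-\t.\tID=g2.1;Parent=g2
"""


class TestGeneModels:
    def test_first_isoform_and_coordinates(self):
        models = parse_gene_models(io.StringIO(GFF))
        assert [m.gene_id for m in models] == ["g1", "g2"]
        g1 = models[0]
        assert g1.isoform_id == "g1.1"  # first mRNA in file order wins
        assert (g1.start, g1.stop) == (100, 200)  # 1-based inclusive -> half-open
        assert models[1].chromosome == "chr2"
        assert models[1].strand == "-"

    def test_orphan_mrna_rejected(self):
        bad = "chr1\tsrc\tmRNA\t1\t10\t.\t+\t.\tID=x.1;Parent=nope\n"
        with pytest.raises(ValueError, match="no parent gene"):
            parse_gene_models(io.StringIO(bad))

    def test_missing_strand_rejected(self):
        bad = "chr1\tsrc\tgene\t1\t10\t.\t.\t.\tID=g\n"
        with pytest.raises(ValueError, match="strand"):
            parse_gene_models(io.StringIO(bad))

    def test_gene_without_mrna_represents_itself(self):
        text = "chr1\tsrc\tgene\t1\t10\t.\t+\t.\tID=solo\n"
        (m,) = parse_gene_models(io.StringIO(text))
        assert m.isoform_id == "solo"


class TestAgp:
    def layout(self):
        return ScaffoldLayout(
            groups={"chrA": [("c1", "+"), ("c2", "-")]},
            unplaced=["c3"],
            within_gap=100,
            unplaced_gap=1000,
        )

    def test_rows_tile_with_gap(self):
        rows = layout_to_agp(
            ScaffoldLayout(groups={"o": [("c1", "+"), ("c2", "+")]}, within_gap=100),
            {"c1": 100, "c2": 100},
        )
        spans = [(r.object_start, r.object_end, r.component_type) for r in rows]
        assert spans == [(1, 100, "W"), (101, 200, "N"), (201, 300, "W")]

    def test_write_read_write_byte_identical(self, tmp_path):
        lengths = {"c1": 120, "c2": 80, "c3": 50}
        rows = layout_to_agp(self.layout(), lengths)
        p1, p2 = tmp_path / "a.agp", tmp_path / "b.agp"
        write_agp(rows, p1)
        write_agp(read_agp(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_layout_round_trip(self, tmp_path):
        lengths = {"c1": 120, "c2": 80, "c3": 50}
        layout = self.layout()
        path = tmp_path / "x.agp"
        write_agp(layout_to_agp(layout, lengths), path)
        back = agp_to_layout(read_agp(path))
        assert back.groups == layout.groups
        assert back.unplaced == layout.unplaced
        assert back.within_gap == layout.within_gap
        assert back.unplaced_gap == layout.unplaced_gap

    def test_minus_row_reverse_complements(self):
        rows = [AgpRow("o", 1, 4, 1, "W", "c1", 1, 4, "-")]
        (rec,) = reconstruct_from_agp(rows, {"c1": "ACGT"})
        assert rec.sequence == revcomp("ACGT") == "ACGT"[::-1].translate(
            str.maketrans("ACGT", "TGCA")
        )

    def test_non_tiling_rows_rejected(self, tmp_path):
        rows = [
            AgpRow("o", 1, 100, 1, "W", "c1", 1, 100, "+"),
            AgpRow("o", 150, 249, 2, "W", "c2", 1, 100, "+"),  # hole at 101-149
        ]
        path = tmp_path / "bad.agp"
        write_agp(rows, path)
        with pytest.raises(ValueError, match="tile"):
            read_agp(path)
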