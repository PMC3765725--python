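"""Data model and format round-trip behaviour."""
import numpy as np
import pytest

from strepnc import io as gio
from strepnc.model import (
    GeneRecord,
    GenomeModel,
    ParseError,
    Replicon,
    StrandedTrack,
    ValidationError,
)

from conftest import make_model


class TestGeneRecord:
    def test_locus_number_from_trailing_digits(self):
        g = GeneRecord("SCO1434", "chr", 0, 100, "+")
        assert g.locus_number == 1434
        assert g.locus_digits == "1434"

    def test_padded_digits_preserved(self):
        assert GeneRecord("S1G0012", "chr", 0, 10, "-").locus_digits == "0012"

    def test_no_digits_flagged_absent(self):
        assert GeneRecord("orfX", "chr", 0, 10, "+").locus_number is None

    @pytest.mark.parametrize(
        "start,end,strand",
        [(100, 100, "+"), (200, 100, "+"), (-1, 10, "+"), (0, 10, "*")],
    )
    def test_invalid_records_rejected(self, start, end, strand):
        with pytest.raises(ValidationError):
            GeneRecord("g", "chr", start, end, strand)

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            make_model([("g1", 0, 10, "+"), ("g1", 20, 30, "+")])

    def test_gene_beyond_replicon_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            make_model([("g1", 0, 3000, "+")], length=2000)


class TestGff3:
    def test_coordinate_convention_conversion(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n##sequence-region chr1 1 5000\n"
            "chr1\tx\tgene\t101\t200\t.\t+\t.\tID=g1\n"
        )
        model = gio.read_gff3(p)
        g = model.gene("g1")
        assert (g.start, g.end, g.strand) == (100, 200, "+")

    def test_empty_feature_file(self, tmp_path):
        p = tmp_path / "e.gff3"
        p.write_text("##gff-version 3\n##sequence-region chr1 1 500\n")
        model = gio.read_gff3(p)
        assert model.genes == []
        assert model.replicons["chr1"].length == 500

    def test_end_before_start_rejected(self, tmp_path):
        p = tmp_path / "b.gff3"
        p.write_text("chr1\tx\tgene\t200\t100\t.\t+\t.\tID=g1\n")
        with pytest.raises(ValidationError, match="end < start"):
            gio.read_gff3(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "m.gff3"
        p.write_text("##gff-version 3\nchr1\tgene\tonly-three-columns\n")
        with pytest.raises(ParseError, match=":2"):
            gio.read_gff3(p)

    def test_round_trip_identity_on_generated_model(self, tmp_path):
        rng = np.random.default_rng(42)
        genes = []
        pos = 0
        for i in range(50):
            length = int(rng.integers(200, 1500))
            fclass = ["protein_coding", "rRNA", "tRNA", "ncRNA"][int(rng.integers(4))]
            genes.append(
                (f"G{i:04d}", pos, pos + length, "+-"[int(rng.integers(2))], fclass)
            )
            pos += length + int(rng.integers(50, 400))
        model = make_model(genes, length=pos + 100)
        p = tmp_path / "rt.gff3"
        gio.write_gff3(model, p)
        again = gio.read_gff3(p)
        assert [
            (g.gene_id, g.start, g.end, g.strand, g.feature_class)
            for g in again.genes
        ] == [
            (g.gene_id, g.start, g.end, g.strand, g.feature_class)
            for g in model.genes
        ]
        assert again.replicons["chr"].length == model.replicons["chr"].length


class TestBedgraph:
    def test_half_open_semantics(self, tmp_path):
        model = make_model([], length=100, rid="chr1")
        p = tmp_path / "c.bedgraph"
        p.write_text("chr1\t10\t13\t5\n")
        depth = gio.read_bedgraph(p, model)["chr1"]
        assert depth[9] == 0
        assert list(depth[10:13]) == [5, 5, 5]
        assert depth[13] == 0

    def test_empty_file_gives_zero_track(self, tmp_path):
        model = make_model([], length=50, rid="chr1")
        p = tmp_path / "e.bedgraph"
        p.write_text("")
        assert gio.read_bedgraph(p, model)["chr1"].sum() == 0

    @pytest.mark.parametrize("line", ["chr1\t10\t200\t5", "chr1\t5\t8\t-2"])
    def test_invalid_records_rejected(self, tmp_path, line):
        model = make_model([], length=100, rid="chr1")
        p = tmp_path / "bad.bedgraph"
        p.write_text(line + "\n")
        with pytest.raises(ValidationError):
            gio.read_bedgraph(p, model)

    def test_round_trip_preserves_every_value(self, tmp_path):
        rng = np.random.default_rng(7)
        model = make_model([], length=400, rid="chr1")
        for trial in range(5):
            depth = rng.integers(0, 30, size=400)
            depth[rng.random(400) < 0.4] = 0  # realistic zero runs
            track = StrandedTrack("chr1", "+", "long", depth)
            p = tmp_path / f"t{trial}.bedgraph"
            gio.write_bedgraph(track, p)
            back = gio.read_bedgraph(p, model)["chr1"]
            np.testing.assert_array_equal(back, depth)


def _write_sam(path, reads, length=200, rid="chr1"):
    """reads: (name, flag, pos0, cigar_len) single-block alignments."""
    lines = [f"@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:{rid}\tLN:{length}"]
    for name, flag, pos0, rlen in reads:
        seq = "A" * rlen
        lines.append(
            f"{name}\t{flag}\t{rid}\t{pos0 + 1}\t60\t{rlen}M\t*\t0\t0\t{seq}\t*"
        )
    path.write_text("\n".join(lines) + "\n")


class TestDepthFromAlignments:
    def test_single_plus_read(self, tmp_path):
        model = make_model([], length=200, rid="chr1")
        sam = tmp_path / "a.sam"
        _write_sam(sam, [("r1", 0, 5, 5)])
        tracks = {(t.strand): t for t in gio.depth_from_alignments(sam, model)}
        assert list(tracks["+"].depth[5:10]) == [1] * 5
        assert tracks["+"].depth.sum() == 5
        assert tracks["-"].depth.sum() == 0

    def test_overlapping_reads_pile_up(self, tmp_path):
        model = make_model([], length=200, rid="chr1")
        sam = tmp_path / "b.sam"
        _write_sam(sam, [("r1", 0, 0, 8), ("r2", 0, 4, 8)])
        plus = {t.strand: t for t in gio.depth_from_alignments(sam, model)}["+"]
        assert list(plus.depth[4:8]) == [2] * 4
        assert list(plus.depth[0:4]) == [1] * 4

    def test_unsorted_input_instructs_to_sort(self, tmp_path):
        model = make_model([], length=200, rid="chr1")
        sam = tmp_path / "u.sam"
        _write_sam(sam, [("r1", 0, 50, 10), ("r2", 0, 5, 10)])
        with pytest.raises(ValidationError, match="sort"):
            gio.depth_from_alignments(sam, model)

    def test_agrees_with_bruteforce_containment_count(self, tmp_path):
        rng = np.random.default_rng(11)
        length = 500
        model = make_model([], length=length, rid="chr1")
        reads = []
        for i in range(100):
            pos = int(rng.integers(0, length - 60))
            rlen = int(rng.integers(20, 60))
            flag = 16 if rng.random() < 0.5 else 0
            reads.append((f"r{i}", flag, pos, rlen))
        reads.sort(key=lambda r: r[2])
        sam = tmp_path / "rnd.sam"
        _write_sam(sam, reads, length=length)
        tracks = {t.strand: t.depth for t in gio.depth_from_alignments(sam, model)}
        expect = {"+": np.zeros(length, int), "-": np.zeros(length, int)}
        for _, flag, pos, rlen in reads:
            strand = "-" if flag & 16 else "+"
            for p in range(pos, pos + rlen):
                expect[strand][p] += 1
        np.testing.assert_array_equal(tracks["+"], expect["+"])
        np.testing.assert_array_equal(tracks["-"], expect["-"])
        # total depth equals total aligned length
        total = sum(r[3] for r in reads)
        assert tracks["+"].sum() + tracks["-"].sum() == total
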