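"""Read-through measurement and antisense classification geometry."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strepnc.antisense import (
    ReadthroughParams,
    classify_gene,
    compute_extents,
    detect_cutorna_pairs,
    detect_divergent_overlap,
    measure_readthrough,
)
from strepnc.model import ValidationError

from conftest import make_model, make_tracks

P = ReadthroughParams(t_rt=10.0)


class TestMeasureReadthrough:
    def test_plus_strand_utr3_scan(self):
        model = make_model([("g1", 100, 400, "+")])
        plus = np.zeros(2000, int)
        plus[100:750] = 30  # body plus read-through to 750
        tracks = make_tracks(model, {("+", "long"): plus})
        ext = measure_readthrough(model, tracks, "g1", P)
        assert ext.utr3 == (400, 750)

    def test_depth_dropping_at_stop_gives_empty_utr3(self):
        model = make_model([("g1", 100, 400, "+")])
        plus = np.zeros(2000, int)
        plus[100:400] = 30
        ext = measure_readthrough(model, make_tracks(model, {("+", "long"): plus}),
                                  "g1", P)
        assert ext.utr3 is None

    def test_sub_floor_gaps_are_bridged(self):
        model = make_model([("g1", 100, 400, "+")])
        plus = np.zeros(2000, int)
        plus[100:700] = 30
        plus[500:504] = 2  # 4 nt dip, tolerance 5
        ext = measure_readthrough(model, make_tracks(model, {("+", "long"): plus}),
                                  "g1", P)
        assert ext.utr3 == (400, 700)

    def test_minus_strand_orientation(self):
        model = make_model([("g1", 600, 900, "-")])
        minus = np.zeros(2000, int)
        minus[450:900] = 30  # 3' read-through runs leftward
        minus[900:950] = 30  # 5' extent runs rightward
        ext = measure_readthrough(model, make_tracks(model, {("-", "long"): minus}),
                                  "g1", P)
        assert ext.utr3 == (450, 600)
        assert ext.utr5 == (900, 950)

    def test_long_readthrough_traversing_whole_gene_is_single_extent(self):
        # a ~1,600 nt read-through crossing one entire opposite-strand gene
        model = make_model(
            [("up", 100, 700, "+"), ("mid", 900, 1400, "-"), ("far", 1700, 2200, "-")],
            length=3000,
        )
        plus = np.zeros(3000, int)
        plus[100:2300] = 25  # read-through 700 -> 2300 (1,600 nt)
        tracks = make_tracks(model, {("+", "long"): plus})
        ext = measure_readthrough(model, tracks, "up", P)
        assert ext.utr3 == (700, 2300)
        calls = detect_cutorna_pairs(model, {"up": ext}, P)
        assert {(c.gene_id, c.partner_gene_id) for c in calls} == {
            ("mid", "up"), ("far", "up")
        }

    def test_unknown_gene_raises(self):
        model = make_model([("g1", 0, 10, "+")])
        with pytest.raises(KeyError):
            measure_readthrough(model, make_tracks(model), "nope", P)


def _cuto_fixture(utr3_end=750, reciprocal=False):
    model = make_model([("A", 100, 400, "+"), ("B", 600, 900, "-")], length=2000)
    plus = np.zeros(2000, int)
    plus[100:utr3_end] = 30
    minus = np.zeros(2000, int)
    minus[600:900] = 40
    if reciprocal:
        minus[250:900] = 40  # B's transcript reads back through A
    tracks = make_tracks(model, {("+", "long"): plus, ("-", "long"): minus})
    return model, tracks


class TestCutornaDetection:
    def test_convergent_overlap_call(self):
        model, tracks = _cuto_fixture()
        extents = compute_extents(model, tracks, P)
        calls = detect_cutorna_pairs(model, extents, P)
        assert len(calls) == 1
        c = calls[0]
        assert (c.gene_id, c.partner_gene_id) == ("B", "A")
        # interval-intersection oracle: [600,900) x [400,750) = [600,750)
        assert (c.start, c.end) == (600, 750)
        assert c.overlap_length == 150

    def test_overlap_below_o_min_not_called(self):
        model, tracks = _cuto_fixture(utr3_end=630)  # 30 nt < o_min 50
        extents = compute_extents(model, tracks, P)
        assert detect_cutorna_pairs(model, extents, P) == []

    def test_reciprocal_readthrough_mirrored_calls(self):
        model, tracks = _cuto_fixture(reciprocal=True)
        extents = compute_extents(model, tracks, P)
        calls = detect_cutorna_pairs(model, extents, P)
        pairs = {(c.gene_id, c.partner_gene_id) for c in calls}
        assert pairs == {("B", "A"), ("A", "B")}

    def test_tandem_pair_never_called(self):
        model = make_model([("A", 100, 400, "+"), ("B", 600, 900, "+")], length=2000)
        plus = np.zeros(2000, int)
        plus[100:900] = 30  # A reads through B on the same strand
        tracks = make_tracks(model, {("+", "long"): plus})
        extents = compute_extents(model, tracks, P)
        assert detect_cutorna_pairs(model, extents, P) == []


class TestDivergentDetection:
    def _fixture(self, gap_covered=True):
        model = make_model([("A", 100, 400, "-"), ("B", 500, 800, "+")], length=2000)
        minus = np.zeros(2000, int)
        minus[100:400] = 30
        plus = np.zeros(2000, int)
        plus[500:800] = 30
        if gap_covered:
            minus[400:560] = 25  # A's 5' UTR crosses into B
            plus[360:500] = 25   # B's 5' UTR crosses into A
        return model, make_tracks(model, {("+", "long"): plus, ("-", "long"): minus})

    def test_overlapping_utr5_extents_call_both_genes(self):
        model, tracks = self._fixture()
        extents = compute_extents(model, tracks, P)
        calls = detect_divergent_overlap(model, extents, P)
        assert {(c.gene_id, c.partner_gene_id) for c in calls} == {
            ("A", "B"), ("B", "A")
        }

    def test_separated_utr5s_not_called(self):
        model, tracks = self._fixture(gap_covered=False)
        extents = compute_extents(model, tracks, P)
        assert detect_divergent_overlap(model, extents, P) == []


class TestClassifyGene:
    def test_island_inside_partner_readthrough_is_cutorna(self):
        model, tracks = _cuto_fixture()
        extents = compute_extents(model, tracks, P)
        calls = classify_gene(model, tracks, "B", True, extents, P)
        assert len(calls) == 1
        assert calls[0].category == "cutoRNA"
        assert calls[0].partner_gene_id == "A"
        assert calls[0].explained_fraction == pytest.approx(1.0)

    def test_sharp_internal_island_is_asrna(self):
        # hopC-style geometry: antisense island in the gene centre, no
        # neighbour read-through
        model = make_model([("g1", 100, 1000, "+")], length=2000)
        minus = np.zeros(2000, int)
        minus[400:600] = 50
        tracks = make_tracks(model, {("-", "long"): minus})
        extents = compute_extents(model, tracks, P)
        calls = classify_gene(model, tracks, "g1", True, extents, P)
        assert [c.category for c in calls] == ["asRNA"]

    def test_diffuse_island_is_unclassified(self):
        model = make_model([("g1", 100, 1000, "+")], length=2000)
        minus = np.zeros(2000, int)
        # slow ramp toward the island's 5' end (right edge on the minus
        # strand): no sharp 5' rise, no partner extents
        minus[300:900] = np.linspace(100, 10, 600).astype(int)
        tracks = make_tracks(model, {("-", "long"): minus})
        extents = compute_extents(model, tracks, P)
        calls = classify_gene(model, tracks, "g1", True, extents, P)
        assert [c.category for c in calls] == ["unclassified"]

    def test_divergent_overlap_plus_independent_asrna_island(self):
        # scbA/scbR-style: a 5' divergent overlap plus a separate internal
        # antisense island on the same gene gives one call of each class
        model = make_model([("A", 100, 700, "-"), ("B", 800, 1400, "+")], length=2000)
        minus = np.zeros(2000, int)
        minus[100:700] = 30
        minus[700:900] = 25    # A's 5' extension into B
        plus = np.zeros(2000, int)
        plus[800:1400] = 30
        plus[640:800] = 25     # B's 5' extension into A
        plus[250:400] = 60     # independent internal antisense island on A
        tracks = make_tracks(model, {("+", "long"): plus, ("-", "long"): minus})
        extents = compute_extents(model, tracks, P)
        calls = classify_gene(model, tracks, "A", True, extents, P)
        assert sorted(c.category for c in calls) == ["asRNA", "divergent_overlap"]

    def test_unflagged_gene_is_a_contract_violation(self):
        model, tracks = _cuto_fixture()
        extents = compute_extents(model, tracks, P)
        with pytest.raises(ValidationError, match="flagged"):
            classify_gene(model, tracks, "B", False, extents, P)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.data())
def test_cutorna_orientation_safety(data):
    """Random annotations never produce a cutoRNA between non-convergent
    genes: every call's partner must be opposite-strand and upstream."""
    n = data.draw(st.integers(2, 5))
    genes, pos = [], 100
    for i in range(n):
        length = data.draw(st.integers(100, 400))
        strand = data.draw(st.sampled_from("+-"))
        genes.append((f"g{i}", pos, pos + length, strand))
        pos += length + data.draw(st.integers(20, 200))
    model = make_model(genes, length=pos + 500)
    rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
    arrays = {
        (s, "long"): (rng.random(pos + 500) < 0.5).astype(int) * 40 for s in "+-"
    }
    tracks = make_tracks(model, arrays)
    extents = compute_extents(model, tracks, P)
    for c in detect_cutorna_pairs(model, extents, P):
        g = model.gene(c.gene_id)
        p = model.gene(c.partner_gene_id)
        assert g.strand != p.strand
        if p.strand == "+":
            assert g.start >= p.end   # partner reads rightward into g
        else:
            assert g.end <= p.start   # partner reads leftward into g
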