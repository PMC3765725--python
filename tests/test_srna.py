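"""Intergenic island finding, UTR disambiguation and sRNA naming."""
import numpy as np
import pytest

from strepnc.model import ValidationError
from strepnc.srna import (
    SrnaCall,
    SrnaParams,
    assign_names,
    call_srnas,
    classify_island,
    find_islands,
    name_srna,
)

from conftest import make_model, make_tracks

P = SrnaParams()


def _island_fixture(depth_plus_short):
    model = make_model([("SCO0100", 100, 400, "+"), ("SCO0200", 1200, 1500, "+")])
    plus = np.zeros(2000, int)
    plus[100:400] = 40
    plus[1200:1500] = 40
    plus += depth_plus_short
    return model, make_tracks(model, {("+", "short"): plus})


class TestFindIslands:
    def test_intergenic_run_becomes_island(self):
        extra = np.zeros(2000, int)
        extra[600:680] = 50
        model, tracks = _island_fixture(extra)
        islands = [i for i in find_islands(model, tracks, P) if i.strand == "+"
                   and 500 < i.start < 700]
        assert len(islands) == 1
        assert (islands[0].start, islands[0].end) == (600, 680)

    def test_small_subfloor_gap_is_merged(self):
        extra = np.zeros(2000, int)
        extra[600:640] = 50
        extra[643:700] = 50  # 3 nt gap < tolerance 5
        model, tracks = _island_fixture(extra)
        islands = [i for i in find_islands(model, tracks, P)
                   if i.strand == "+" and 500 < i.start < 700]
        assert [(i.start, i.end) for i in islands] == [(600, 700)]

    def test_run_touching_a_gene_is_excluded_from_intergenic_space(self):
        extra = np.zeros(2000, int)
        extra[399:480] = 50  # overlaps SCO0100 by 1 nt
        model, tracks = _island_fixture(extra)
        islands = [i for i in find_islands(model, tracks, P)
                   if i.strand == "+" and i.start < 500]
        # the island is clipped at the gene boundary, never across it
        assert all(i.start >= 400 for i in islands)

    def test_island_found_in_long_library_alone(self):
        # scr3716-style: represented in the long-transcript library only
        model = make_model([("g1", 100, 400, "+")])
        long_plus = np.zeros(2000, int)
        long_plus[800:928] = 60
        tracks = make_tracks(model, {("+", "long"): long_plus})
        islands = [i for i in find_islands(model, tracks, P) if i.strand == "+"]
        assert [(i.start, i.end) for i in islands] == [(800, 928)]
        assert islands[0].mean_depth["short"] == 0.0

    def test_raising_floor_nests_islands_and_shrinks_coverage(self, sim_result):
        """Raising t_isl is monotone at the island level: every island found
        at a higher floor lies inside one found at a lower floor, and the
        total island-covered length never grows.  (The *call* count is not
        monotone: a higher floor also erodes the coverage continuity that
        links UTR fragments to their gene, so suppressed islands can
        re-emerge as sRNA calls.)"""
        sp = "S1"
        model, tracks = sim_result.models[sp], sim_result.tracks[sp]
        previous = None
        for floor in (10.0, 20.0, 40.0):
            islands = find_islands(model, tracks, SrnaParams(island_floor=floor))
            if previous is not None:
                for hi in islands:
                    assert any(
                        lo.replicon_id == hi.replicon_id
                        and lo.strand == hi.strand
                        and lo.start <= hi.start
                        and hi.end <= lo.end
                        for lo in previous
                    )
                assert sum(i.length for i in islands) <= sum(
                    i.length for i in previous
                )
            previous = islands


class TestClassifyIsland:
    def _classify(self, model, tracks, start, end, strand="+"):
        islands = [
            i for i in find_islands(model, tracks, P)
            if i.start == start and i.end == end and i.strand == strand
        ]
        assert islands, "expected island not found"
        return classify_island(islands[0], model, tracks, P)

    def test_length_below_minimum_rejected_not_dropped(self):
        extra = np.zeros(2000, int)
        extra[600:639] = 50  # 39 nt < 40
        model, tracks = _island_fixture(extra)
        call = self._classify(model, tracks, 600, 639)
        assert call.classification == "sRNA"
        assert call.rejected

    def test_sodf_geometry_strong_island_near_gene_end_is_srna(self):
        # 18 nt downstream of a gene, 10x the gene's 3' depth: proximity
        # alone must not disqualify it
        model = make_model([("sodF", 100, 400, "+")])
        plus = np.zeros(2000, int)
        plus[100:400] = 20
        plus[418:500] = 200
        tracks = make_tracks(model, {("+", "short"): plus})
        call = self._classify(model, tracks, 418, 500)
        assert call.classification == "sRNA"
        assert not call.rejected

    def test_weak_trailing_island_continuous_with_gene_is_utr3(self):
        model = make_model([("g1", 100, 400, "+")])
        plus = np.zeros(2000, int)
        plus[100:400] = 100
        plus[400:460] = 30  # continuous, well below 5x the 3' depth
        tracks = make_tracks(model, {("+", "short"): plus})
        call = self._classify(model, tracks, 400, 460)
        assert call.classification == "utr3_fragment"
        assert call.linked_gene_id == "g1"

    def test_island_continuous_into_downstream_gene_start_is_utr5(self):
        model = make_model([("g1", 1200, 1500, "+")])
        plus = np.zeros(2000, int)
        plus[1200:1500] = 40
        plus[1100:1188] = 60
        plus[1188:1200] = 30  # bridge: 12 nt away but continuously covered
        tracks = make_tracks(model, {("+", "short"): plus})
        calls = [
            classify_island(i, model, tracks, P)
            for i in find_islands(model, tracks, P)
            if i.strand == "+"
        ]
        assert calls[0].classification == "utr5_fragment"
        assert calls[0].linked_gene_id == "g1"


class TestNaming:
    def _call(self, start, end):
        return SrnaCall("chr", start, end, "+", "sRNA")

    def test_name_from_right_flanking_gene(self):
        model = make_model([("SCO1434", 1200, 1500, "+")])
        assert name_srna(self._call(600, 680), model, "scr") == "scr1434"

    def test_chromosome_end_falls_back_to_left_flank_with_marker(self):
        model = make_model([("SVEN0001", 100, 400, "+")])
        assert name_srna(self._call(600, 680), model, "svr") == "svr0001L"

    def test_svr_prefix_composition(self):
        model = make_model([("SVEN5535", 1200, 1500, "+")])
        assert name_srna(self._call(600, 641), model, "svr") == "svr5535"

    def test_collision_suffixes_in_coordinate_order(self):
        model = make_model([("SCO0999", 1200, 1500, "+")])
        named = assign_names(
            [self._call(700, 780), self._call(500, 580)], model, "scr"
        )
        assert [c.name for c in named] == ["scr0999a", "scr0999b"]
        assert named[0].start == 500  # coordinate order, not input order

    def test_non_coding_flank_is_skipped(self):
        model = make_model(
            [("rrnA1", 800, 900, "+", "rRNA"), ("SCO2000", 1200, 1500, "+")]
        )
        assert name_srna(self._call(600, 680), model, "scr") == "scr2000"

    def test_no_flank_at_all_raises(self):
        model = make_model([("noDigitsGene", 1200, 1500, "+")])
        with pytest.raises(ValidationError):
            name_srna(self._call(600, 680), model, "scr")


def test_no_emitted_srna_overlaps_any_gene(sim_result):
    """Interval-intersection assertion over every call on the fixture."""
    for sp, model in sim_result.models.items():
        calls, _ = call_srnas(model, sim_result.tracks[sp], P, "scr")
        for c in calls:
            assert not model.genes_overlapping(c.replicon_id, c.start, c.end)
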