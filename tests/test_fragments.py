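"""Stable-fragment detection, location classes and content analysis."""
import numpy as np
import pytest

from strepnc.fragments import (
    FragmentParams,
    StableRegion,
    classify_location,
    codon_usage_table,
    content_analysis,
    detect_stable_regions,
    rank_stable_regions,
    rare_codons,
)
from strepnc.model import GeneRecord

from conftest import make_model, make_tracks


def _gene_with_region(baseline=4, region=(300, 360), region_depth=500,
                      gene=(100, 1000), strand="+"):
    model = make_model([("g1", gene[0], gene[1], strand)], length=2000)
    depth = np.zeros(2000, int)
    depth[gene[0]:gene[1]] = baseline
    depth[region[0]:region[1]] = region_depth
    return model, make_tracks(model, {(strand, "short"): depth})


class TestDetection:
    def test_region_above_strict_fold_detected(self):
        model, tracks = _gene_with_region(baseline=4, region_depth=500)
        regions = detect_stable_regions(model, tracks)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (300, 360)
        assert r.fold_enrichment == pytest.approx(125.0)
        assert r.location_class == "internal"

    def test_uniform_coverage_gene_yields_nothing(self):
        model = make_model([("g1", 100, 1000, "+")], length=2000)
        depth = np.zeros(2000, int)
        depth[100:1000] = 40
        tracks = make_tracks(model, {("+", "short"): depth})
        assert detect_stable_regions(model, tracks) == []

    def test_ninety_five_fold_not_detected(self):
        model, tracks = _gene_with_region(baseline=4, region_depth=380)  # 95x
        assert detect_stable_regions(model, tracks) == []

    def test_short_region_below_min_len_skipped(self):
        model, tracks = _gene_with_region(region=(300, 315), region_depth=500)
        assert detect_stable_regions(model, tracks) == []

    def test_zero_baseline_floored_and_flagged(self):
        # gene body absent from the short library entirely
        model = make_model([("g1", 100, 1000, "+")], length=2000)
        depth = np.zeros(2000, int)
        depth[300:360] = 500
        tracks = make_tracks(model, {("+", "short"): depth})
        regions = detect_stable_regions(model, tracks)
        assert len(regions) == 1
        assert regions[0].baseline == 1.0
        assert regions[0].baseline_floored

    def test_detection_invariant_under_uniform_scaling(self):
        model, tracks1 = _gene_with_region(baseline=3, region_depth=450)
        _, tracks10 = _gene_with_region(baseline=30, region_depth=4500)
        r1 = detect_stable_regions(model, tracks1)
        r10 = detect_stable_regions(model, tracks10)
        assert [(r.start, r.end) for r in r1] == [(r.start, r.end) for r in r10]
        assert r1[0].fold_enrichment == pytest.approx(r10[0].fold_enrichment, rel=0.01)

    def test_reported_fold_exceeds_min_fold_reassertable_from_output(self):
        model, tracks = _gene_with_region()
        for r in detect_stable_regions(model, tracks):
            assert r.fold_enrichment > FragmentParams().min_fold


class TestLocationClass:
    GENE = GeneRecord("g", "chr", 100, 1000, "+")

    def test_region_at_transcript_start_is_utr5(self):
        assert classify_location((100, 160), self.GENE) == "utr5"

    def test_internal_region_far_from_both_ends(self):
        assert classify_location((400, 462), self.GENE) == "internal"

    def test_region_at_transcript_end_is_utr3(self):
        assert classify_location((960, 1000), self.GENE) == "utr3_or_intergenic_operon"

    def test_minus_strand_ends_swap(self):
        g = GeneRecord("g", "chr", 100, 1000, "-")
        assert classify_location((960, 1000), g) == "utr5"
        assert classify_location((100, 160), g) == "utr3_or_intergenic_operon"

    def test_five_prime_plus_internal_pair(self):
        # sven2374-style geometry: a 5'-end region and a separate 62 nt
        # internal region on the same gene yield exactly those two classes
        model = make_model([("g1", 100, 1000, "+")], length=2000)
        depth = np.zeros(2000, int)
        depth[100:1000] = 4
        depth[100:150] = 900
        depth[500:562] = 900
        tracks = make_tracks(model, {("+", "short"): depth})
        regions = detect_stable_regions(model, tracks)
        assert sorted(r.location_class for r in regions) == ["internal", "utr5"]


class TestContentAnalysis:
    def _model(self, seq):
        return make_model([("g1", 0, len(seq), "+")], length=len(seq), sequence=seq)

    def test_pure_at_upstream_window(self):
        seq = "ATATATATATATATA" + "G" * 60 + "GCC" * 10
        model = self._model(seq)
        region = StableRegion("g1", "chr", 15, 75, "+", "internal", 200.0, 1.0)
        usage = codon_usage_table(model)
        stats = content_analysis(region, model, usage)
        assert stats.at_upstream_window == 1.0

    def test_uniform_gc_region_equals_cds(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(["G", "C"], size=300))
        model = self._model(seq)
        region = StableRegion("g1", "chr", 100, 160, "+", "internal", 200.0, 1.0)
        stats = content_analysis(region, model, codon_usage_table(model))
        assert stats.gc_region == 1.0
        assert stats.gc_cds == 1.0
        assert stats.at_cds == 0.0

    def test_window_truncated_near_transcript_start(self):
        seq = "A" * 300
        model = self._model(seq)
        region = StableRegion("g1", "chr", 5, 60, "+", "utr5", 200.0, 1.0)
        stats = content_analysis(region, model, codon_usage_table(model))
        assert stats.window_truncated

    def test_rare_codons_are_bottom_quartile(self):
        # genome of a single gene using GCC for Ala throughout; GCA/GCG/GCT
        # unused and therefore rare, GCC not
        seq = "ATG" + "GCC" * 50 + "TAA"
        usage = codon_usage_table(self._model(seq))
        rare = rare_codons(usage)
        assert "GCA" in rare and "GCC" not in rare


class TestRanking:
    def _region(self, gene, start, fold):
        return StableRegion(gene, "chr", start, start + 50, "+", "internal", fold, 1.0)

    def test_top_k_with_full_sort_oracle(self):
        rng = np.random.default_rng(8)
        regions = [
            self._region(f"g{i}", int(rng.integers(0, 5000)), float(rng.uniform(101, 900)))
            for i in range(25)
        ]
        top = rank_stable_regions(regions, k=20)
        oracle = sorted(regions, key=lambda r: (-r.fold_enrichment, r.gene_id, r.start))
        assert top == oracle[:20]
        assert top[0].fold_enrichment == max(r.fold_enrichment for r in regions)

    def test_ties_break_deterministically(self):
        regions = [self._region("gB", 10, 200.0), self._region("gA", 10, 200.0)]
        assert [r.gene_id for r in rank_stable_regions(regions, 2)] == ["gA", "gB"]

    def test_k_larger_than_available_returns_all(self):
        regions = [self._region("g", 0, 150.0)]
        assert rank_stable_regions(regions, 20) == regions
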