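"""Detection and annotation of stable intragenic RNA fragments.

The short-transcript library is size-selected, so RNA segments resistant
to decay (structured UTR elements, internal hairpins, termination
sequences) pile up far above the rest of their parent mRNA.  A region is
called when its mean short-library sense depth exceeds ``min_fold``
(strictly, >100-fold by default) times the gene-body baseline.

The baseline is the mean over the gene *excluding* candidate windows: a
masking pass first identifies enriched runs with a deliberately low bar
(``mask_fold`` times the gene median — a strong region inflates the naive
mean enough to hide itself, and can occupy enough of a short gene to
drag even a mean-based mask bar above its own depth), the baseline is
then estimated on the unmasked remainder, and the strict fold test is
applied to each candidate's mean against that baseline.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import merge_close, runs_true
from .model import GenomeModel, GeneRecord, TrackSet, ValidationError

LOCATION_CLASSES = ("utr5", "utr3_or_intergenic_operon", "internal")


@dataclass(frozen=True)
class FragmentParams:
    min_fold: float = 100.0   # strict: region mean must exceed this x baseline
    min_len: int = 20         # nt
    mask_fold: float = 5.0    # candidate-window bar, x gene median depth
    gap_tolerance: int = 3    # nt of sub-bar signal bridged inside a run
    end_zone: int = 25        # nt defining the 5'/3' end-associated classes
    use_max: bool = False     # compare region max (not mean) to baseline


@dataclass(frozen=True)
class StableRegion:
    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    location_class: str
    fold_enrichment: float
    baseline: float
    baseline_floored: bool = False

    def __post_init__(self) -> None:
        if self.fold_enrichment <= 0:
            raise ValidationError("fold enrichment must be positive")
        if self.location_class not in LOCATION_CLASSES:
            raise ValidationError(f"bad location class {self.location_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class NucleotideStats:
    """Nucleotide and codon context of one stable region.

    ``at_upstream_window`` is measured over the ``window`` nt immediately
    5' of the region in transcript orientation; rare codons are the bottom
    quartile of relative synonymous codon usage computed genome-wide.
    """

    gc_region: float
    gc_cds: float
    at_upstream_window: float
    at_cds: float
    rare_codon_fraction_upstream: float
    rare_codon_fraction_region: float
    window: int = 15
    window_truncated: bool = False


def detect_stable_regions(
    model: GenomeModel,
    tracks: TrackSet,
    params: FragmentParams = FragmentParams(),
    library: str = "short",
) -> list[StableRegion]:
    """Regions of a gene grossly over-represented in the short library.

    A zero baseline (gene body absent from the short library) is floored
    at 1 read per base and the region flagged, so fold enrichment never
    divides by zero.
    """
    regions = []
    for g in model.genes:
        depth = tracks.depth(g.replicon_id, g.strand, library)[g.start : g.end]
        if depth.size == 0:
            continue
        # candidate windows: runs above a low bar relative to the gene
        # median (robust to the enriched region inflating the mean), with
        # an absolute floor so silent genes yield no candidates
        med = float(np.median(depth))
        mask_bar = max(params.mask_fold * med, params.mask_fold)
        candidates = merge_close(
            runs_true(depth >= mask_bar), params.gap_tolerance
        )
        masked = np.zeros(depth.size, dtype=bool)
        for s, e in candidates:
            masked[s:e] = True
        rest = depth[~masked]
        baseline = float(rest.mean()) if rest.size else 0.0
        floored = False
        if baseline <= 0:
            baseline, floored = 1.0, True
        for s, e in candidates:
            if e - s < params.min_len:
                continue
            stat = float(depth[s:e].max()) if params.use_max else float(depth[s:e].mean())
            fold = stat / baseline
            if fold <= params.min_fold:  # strict: "more than"
                continue
            regions.append(
                StableRegion(
                    gene_id=g.gene_id,
                    replicon_id=g.replicon_id,
                    start=g.start + s,
                    end=g.start + e,
                    strand=g.strand,
                    location_class=classify_location(
                        (g.start + s, g.start + e), g, params.end_zone
                    ),
                    fold_enrichment=fold,
                    baseline=baseline,
                    baseline_floored=floored,
                )
            )
    return regions


def classify_location(
    region: tuple[int, int], gene: GeneRecord, end_zone: int = 25
) -> str:
    """5' end-associated / 3' end-associated (or operon-internal
    intergenic) / internal, by overlap with the ``end_zone`` nt at each
    transcript end."""
    s, e = region
    if gene.strand == "+":
        five = (gene.start, gene.start + end_zone)
        three = (gene.end - end_zone, gene.end)
    else:
        five = (gene.end - end_zone, gene.end)
        three = (gene.start, gene.start + end_zone)
    if s < five[1] and five[0] < e:
        return "utr5"
    if s < three[1] and three[0] < e:
        return "utr3_or_intergenic_operon"
    return "internal"


# ---------------------------------------------------------------------------
# Nucleotide / codon content

def codon_usage_table(model: GenomeModel) -> dict[str, float]:
    """Relative synonymous codon usage from all annotated protein-coding
    genes: each codon's frequency within its synonymous family."""
    from Bio.Seq import Seq

    counts: dict[str, int] = {}
    for g in model.genes:
        if g.feature_class != "protein_coding":
            continue
        seq = _transcript(model, g)
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                continue
            counts[codon] = counts.get(codon, 0) + 1
    by_aa: dict[str, list[str]] = {}
    for codon in _all_codons():
        aa = str(Seq(codon).translate())
        by_aa.setdefault(aa, []).append(codon)
    usage = {}
    for aa, codons in by_aa.items():
        total = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            usage[c] = counts.get(c, 0) / total if total else 0.0
    return usage


def rare_codons(usage: dict[str, float]) -> set[str]:
    """Bottom quartile of relative synonymous usage ('poorly-used codons')."""
    values = sorted(usage.values())
    cutoff = values[len(values) // 4]
    return {c for c, u in usage.items() if u <= cutoff}


def _all_codons():
    bases = "ACGT"
    return [a + b + c for a in bases for b in bases for c in bases]


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _transcript(model: GenomeModel, gene: GeneRecord) -> str:
    seq = model.sequence(gene.replicon_id)[gene.start : gene.end].upper()
    return seq if gene.strand == "+" else _revcomp(seq)


def _gc(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(c in "GC" for c in seq) / len(seq)


def content_analysis(
    region: StableRegion,
    model: GenomeModel,
    usage: dict[str, float],
    window: int = 15,
) -> NucleotideStats:
    """GC/AT and rare-codon context of one region and its upstream window.

    All intervals are taken in transcript orientation; the upstream window
    is truncated (and flagged) when the region sits within ``window`` nt of
    the transcript 5' end.  Codon fractions consider in-frame codons only,
    relative to the gene's reading frame.
    """
    gene = model.gene(region.gene_id)
    t = _transcript(model, gene)
    if gene.strand == "+":
        r0, r1 = region.start - gene.start, region.end - gene.start
    else:
        r0, r1 = gene.end - region.end, gene.end - region.start
    w0 = max(0, r0 - window)
    truncated = (r0 - w0) < window
    region_seq = t[r0:r1]
    window_seq = t[w0:r0]
    rare = rare_codons(usage)

    def rare_fraction(lo: int, hi: int) -> float:
        first = lo + (-lo) % 3  # first in-frame codon start at/after lo
        codons = [
            t[i : i + 3] for i in range(first, hi - 2, 3)
        ]
        codons = [c for c in codons if len(c) == 3 and "N" not in c]
        if not codons:
            return 0.0
        return sum(c in rare for c in codons) / len(codons)

    return NucleotideStats(
        gc_region=_gc(region_seq),
        gc_cds=_gc(t),
        at_upstream_window=1.0 - _gc(window_seq) if window_seq else 0.0,
        at_cds=1.0 - _gc(t),
        rare_codon_fraction_upstream=rare_fraction(w0, r0),
        rare_codon_fraction_region=rare_fraction(r0, r1),
        window=window,
        window_truncated=truncated,
    )


def rank_stable_regions(
    regions: list[StableRegion], k: int = 20
) -> list[StableRegion]:
    """Top-k regions by fold enrichment, deterministic tie-break by
    (gene_id, start); asks for more than exist -> all of them."""
    ranked = sorted(
        regions, key=lambda r: (-r.fold_enrichment, r.gene_id, r.start)
    )
    return ranked[: min(k, len(ranked))]


def regions_to_dataframe(
    regions: list[StableRegion],
    stats: list[NucleotideStats] | None = None,
) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(regions):
        row = {
            "gene_id": r.gene_id,
            "replicon_id": r.replicon_id,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "length": r.length,
            "location_class": r.location_class,
            "fold_enrichment": r.fold_enrichment,
            "baseline": r.baseline,
            "baseline_floored": r.baseline_floored,
        }
        if stats is not None:
            st = stats[i]
            row.update(
                gc_region=st.gc_region,
                gc_cds=st.gc_cds,
                at_upstream_window=st.at_upstream_window,
                at_cds=st.at_cds,
                rare_codon_fraction_upstream=st.rare_codon_fraction_upstream,
                rare_codon_fraction_region=st.rare_codon_fraction_region,
            )
        rows.append(row)
    return pd.DataFrame(rows)
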