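"""Per-gene sense/antisense coverage statistics and candidacy thresholds.

The central quantity is the mean expression value (MEV): the average read
depth per nucleotide over a gene interval on a given strand.  Antisense
candidacy combines the MEV with the peak per-base antisense depth; both
thresholds scale between species in proportion to the number of
non-ribosomal mapped reads, with the peak threshold fixed at twice the MEV
threshold.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .model import GenomeModel, TrackSet, ValidationError, opposite

#: Peak threshold is twice the MEV threshold (consistent with the triples
#: 10.0/20.0, 3.45/6.9 and 4.1/8.2).
PEAK_TO_MEV_RATIO = 2.0


def display_round(value: float, ndigits: int = 1) -> float:
    """Round half-up at ``ndigits`` decimals for display (3.45 -> 3.5).

    Plain ``round`` on binary floats would turn 3.45 into 3.4; thresholds
    are quoted at one decimal, so displayed values use decimal half-up on
    the value pre-rounded to 9 significant decimals.
    """
    d = Decimal(repr(round(value, 9))).quantize(
        Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP
    )
    return float(d)


@dataclass(frozen=True)
class GeneCoverageStats:
    """Sense/antisense MEV and antisense peak for one gene in one library."""

    gene_id: str
    library: str
    mev_sense: float
    mev_antisense: float
    peak_antisense: int

    def __post_init__(self) -> None:
        if min(self.mev_sense, self.mev_antisense, self.peak_antisense) < 0:
            raise ValidationError(f"negative coverage statistic for {self.gene_id}")
        if self.peak_antisense < self.mev_antisense:
            raise ValidationError(
                f"{self.gene_id}: peak antisense below mean antisense"
            )


@dataclass(frozen=True)
class ThresholdSet:
    """Antisense candidacy thresholds for one species.

    ``t_mev`` applies to the antisense MEV, ``t_peak`` to the peak per-base
    antisense depth; both are strict (">") cutoffs.  ``nonrrna_reads`` is
    the non-ribosomal mapped read count the thresholds were scaled by,
    when known.
    """

    species: str
    t_mev: float
    t_peak: float
    nonrrna_reads: int | None = None

    def __post_init__(self) -> None:
        if self.t_mev <= 0 or self.t_peak <= 0:
            raise ValidationError("thresholds must be positive")

    @property
    def t_mev_display(self) -> float:
        return display_round(self.t_mev)

    @property
    def t_peak_display(self) -> float:
        return display_round(self.t_peak)


def compute_gene_stats(
    model: GenomeModel, tracks: TrackSet, library: str
) -> list[GeneCoverageStats]:
    """Sense/antisense MEV and antisense peak for every gene in ``model``.

    Means are computed as integer depth totals divided by gene length in a
    single division, so they agree exactly with a per-position summation.
    """
    if not tracks.covers(model, library):
        missing = [
            rid for rid in model.replicons
            if not all((rid, s, library) in tracks._d for s in ("+", "-"))
        ]
        raise ValidationError(
            f"tracks missing for library {library!r} on replicons {missing}"
        )
    out = []
    for g in model.genes:
        sense = tracks.depth(g.replicon_id, g.strand, library)
        anti = tracks.depth(g.replicon_id, opposite(g.strand), library)
        s_seg = sense[g.start : g.end]
        a_seg = anti[g.start : g.end]
        out.append(
            GeneCoverageStats(
                gene_id=g.gene_id,
                library=library,
                mev_sense=int(s_seg.sum()) / g.length,
                mev_antisense=int(a_seg.sum()) / g.length,
                peak_antisense=int(a_seg.max()) if g.length else 0,
            )
        )
    return out


def derive_thresholds(
    reference: ThresholdSet,
    nonrrna_reads_by_species: dict[str, float] | None = None,
    factors: dict[str, float] | None = None,
) -> dict[str, ThresholdSet]:
    """Scale a reference threshold pair to other species.

    ``t_mev(s) = reference.t_mev * f(s)`` where the factor ``f(s)`` is
    either given directly or derived as
    ``nonrrna_reads(s) / nonrrna_reads(reference)``; the peak threshold is
    always ``PEAK_TO_MEV_RATIO * t_mev``.  Full precision is kept
    internally; the ``*_display`` properties round to one decimal.
    """
    if (nonrrna_reads_by_species is None) == (factors is None):
        raise ValidationError(
            "provide exactly one of nonrrna_reads_by_species or factors"
        )
    if factors is None:
        counts = nonrrna_reads_by_species
        if reference.species not in counts:
            raise ValidationError(
                f"reference species {reference.species!r} missing from counts"
            )
        if any(c <= 0 for c in counts.values()):
            raise ValidationError("read counts must be positive")
        ref_count = counts[reference.species]
        factors = {s: c / ref_count for s, c in counts.items()}
        counts_known = counts
    else:
        if any(f <= 0 for f in factors.values()):
            raise ValidationError("scaling factors must be positive")
        counts_known = {}
    out = {}
    for species, f in factors.items():
        t_mev = reference.t_mev * f
        out[species] = ThresholdSet(
            species=species,
            t_mev=t_mev,
            t_peak=PEAK_TO_MEV_RATIO * t_mev,
            nonrrna_reads=counts_known.get(species),
        )
    return out


def flag_antisense_candidates(
    stats: list[GeneCoverageStats], thresholds: ThresholdSet
) -> set[str]:
    """Genes whose antisense MEV or peak exceeds its threshold (strict >).

    Candidacy is the disjunction of the two rules: a short but strong
    antisense island can flag a long gene through the peak rule even when
    the gene-wide MEV stays low.
    """
    return {
        s.gene_id
        for s in stats
        if s.mev_antisense > thresholds.t_mev or s.peak_antisense > thresholds.t_peak
    }


def stats_table(
    stats: list[GeneCoverageStats], thresholds: ThresholdSet | None = None
) -> pd.DataFrame:
    """Flat TSV-ready table of per-gene statistics (plus flag column)."""
    rows = [
        {
            "gene_id": s.gene_id,
            "library": s.library,
            "mev_sense": s.mev_sense,
            "mev_antisense": s.mev_antisense,
            "peak_antisense": s.peak_antisense,
        }
        for s in stats
    ]
    df = pd.DataFrame(rows)
    if thresholds is not None and len(df):
        flagged = flag_antisense_candidates(stats, thresholds)
        df["flagged"] = df["gene_id"].isin(flagged)
    return df
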