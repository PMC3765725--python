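"""Scoring of pipeline calls against the planted ground truth of a
synthetic fixture: per-class recovery rates, false-call counts, and
whether the computed cross-species conservation pattern reproduces the
planted homology truth table."""
from __future__ import annotations

from dataclasses import dataclass

from .antisense import AntisenseCall
from .model import GenomeModel
from .simulate import PlantedFeature
from .srna import SrnaCall


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0


@dataclass
class RecoveryReport:
    n_planted: int
    n_recovered: int

    @property
    def fraction(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else 1.0

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def score_antisense(
    features: list[PlantedFeature], calls: list[AntisenseCall]
) -> dict[str, RecoveryReport]:
    """Recovery per planted antisense class.

    A planted feature is recovered when some primary call on the same gene
    carries the planted category, and — for cutoRNA / divergent_overlap —
    names the planted partner gene.
    """
    out: dict[str, RecoveryReport] = {}
    for kind in ("asRNA", "cutoRNA", "divergent_overlap"):
        planted = [f for f in features if f.kind == kind]
        n_rec = 0
        for f in planted:
            for c in calls:
                if c.gene_id != f.gene_id or c.category != kind:
                    continue
                if kind != "asRNA" and c.partner_gene_id != f.partner_gene_id:
                    continue
                n_rec += 1
                break
        out[kind] = RecoveryReport(len(planted), n_rec)
    return out


def score_srnas(
    features: list[PlantedFeature],
    calls: list[SrnaCall],
    model: GenomeModel,
    min_overlap: float = 0.5,
) -> tuple[RecoveryReport, int, dict[str, str]]:
    """sRNA recovery plus intragenic false-call count.

    Returns (recovery, n_calls_overlapping_any_gene, planted feature id ->
    call name map).  Matching is same replicon/strand with reciprocal
    overlap >= min_overlap.
    """
    planted = [f for f in features if f.kind == "sRNA"]
    mapping: dict[str, str] = {}
    for f in planted:
        for c in calls:
            if (
                c.replicon_id == f.replicon_id
                and c.strand == f.strand
                and _reciprocal_overlap((f.start, f.end), (c.start, c.end))
                >= min_overlap
            ):
                mapping[f.feature_id] = c.name
                break
    n_intragenic = sum(
        1
        for c in calls
        if model.genes_overlapping(c.replicon_id, c.start, c.end)
    )
    return RecoveryReport(len(planted), len(mapping)), n_intragenic, mapping


def score_stable_regions(
    features: list[PlantedFeature],
    regions: list,
    min_overlap: float = 0.5,
) -> tuple[RecoveryReport, int]:
    """Stable-region recovery (correct host gene, location class and
    interval) plus the number of 50x decoys wrongly detected."""
    planted = [f for f in features if f.kind.startswith("stable_region")]
    n_rec = 0
    for f in planted:
        for r in regions:
            if (
                r.gene_id == f.gene_id
                and r.location_class == f.location_class
                and _reciprocal_overlap((f.start, f.end), (r.start, r.end))
                >= min_overlap
            ):
                n_rec += 1
                break
    decoys = [f for f in features if f.kind == "stable_decoy"]
    n_decoy_hits = sum(
        1
        for f in decoys
        for r in regions
        if r.gene_id == f.gene_id
        and _reciprocal_overlap((f.start, f.end), (r.start, r.end)) >= min_overlap
    )
    return RecoveryReport(len(planted), n_rec), n_decoy_hits


def conservation_matches_truth(
    features: list[PlantedFeature],
    call_map_by_species: dict[str, dict[str, str]],
    conserved_in: dict[str, frozenset[str]],
) -> tuple[bool, int, int]:
    """Does the computed conservation pattern equal the planted one?

    ``call_map_by_species[sp]`` maps planted feature ids to call names for
    species ``sp``; ``conserved_in`` maps call names to the set of other
    species they were linked to.  Returns (all_equal, n_matching, n_total):
    every planted sRNA must be matched by a call whose computed pattern
    equals its planted ``conserved_in`` set.
    """
    n_total = 0
    n_match = 0
    for f in features:
        if f.kind != "sRNA":
            continue
        n_total += 1
        name = call_map_by_species.get(f.species, {}).get(f.feature_id)
        if name is None:
            continue
        if conserved_in.get(name, frozenset()) == f.conserved_in:
            n_match += 1
    return n_match == n_total, n_match, n_total
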