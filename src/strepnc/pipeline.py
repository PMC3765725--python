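"""End-to-end pipeline: coverage -> antisense classification -> sRNA
calling -> cross-species conservation -> stable fragments -> reports.

Stages run per species and write TSV/GFF3 outputs plus a YAML manifest
under the configured output directory.  Stage logs go to stderr; machine
output never mixes into logs.  Reruns with the same inputs and
configuration are byte-identical.
"""
from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as gio
from .antisense import (
    AntisenseCall,
    ReadthroughParams,
    TranscribedExtent,
    calls_to_dataframe,
    calls_to_gff3,
    classify_antisense,
)
from .config import RunConfig, SpeciesConfig, write_manifest
from .conserve import (
    HomologyHit,
    build_homology_sets,
    compartment_summary,
    links_from_alignment,
    venn_counts,
)
from .coverage import ThresholdSet, compute_gene_stats, flag_antisense_candidates, stats_table
from .fragments import (
    codon_usage_table,
    content_analysis,
    detect_stable_regions,
    rank_stable_regions,
    regions_to_dataframe,
)
from .model import GenomeModel, TrackSet, ValidationError
from .report import annotate_clusters, clusters_to_dataframe
from .srna import SrnaCall, call_srnas, srnas_to_dataframe, srnas_to_gff3

log = logging.getLogger("strepnc")

STAGES = ("coverage", "antisense", "srna", "conservation", "stable", "report")


@dataclass
class SpeciesData:
    """In-memory inputs for one species."""

    label: str
    model: GenomeModel
    tracks: TrackSet
    clusters: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class SpeciesResult:
    stats: list = field(default_factory=list)
    thresholds: ThresholdSet | None = None
    flagged: set[str] = field(default_factory=set)
    primary_calls: list[AntisenseCall] = field(default_factory=list)
    pair_calls: list[AntisenseCall] = field(default_factory=list)
    extents: dict[str, TranscribedExtent] = field(default_factory=dict)
    srnas: list[SrnaCall] = field(default_factory=list)
    companions: list[SrnaCall] = field(default_factory=list)
    regions: list = field(default_factory=list)
    cluster_annotations: list = field(default_factory=list)
    cluster_antisense_fraction: float | None = None


@dataclass
class PipelineResult:
    config: RunConfig
    species: dict[str, SpeciesResult]
    links: set[tuple[str, str]] = field(default_factory=set)
    hits: list[HomologyHit] = field(default_factory=list)
    conserved_in: dict[str, frozenset[str]] = field(default_factory=dict)
    venn: dict = field(default_factory=dict)
    summaries: dict[str, object] = field(default_factory=dict)


def load_species_data(sp: SpeciesConfig) -> SpeciesData:
    """Load one species from a fixture-layout directory (annotation.gff3,
    genome.fna, {long,short}_{plus,minus}.bedgraph, compartments.bed,
    clusters.bed)."""
    if sp.fixture_dir is None:
        raise ValidationError(f"species {sp.label}: no fixture_dir configured")
    d = Path(sp.fixture_dir)
    for required in ("annotation.gff3", "long_plus.bedgraph"):
        if not (d / required).is_file():
            raise FileNotFoundError(f"missing input file: {d / required}")
    model = gio.read_gff3(d / "annotation.gff3")
    if (d / "genome.fna").is_file():
        gio.read_fasta(d / "genome.fna", model)
    if (d / "compartments.bed").is_file():
        model.compartments = gio.compartments_from_bed(d / "compartments.bed", model)
        model.validate()
    tracks = []
    for lib in ("long", "short"):
        plus, minus = d / f"{lib}_plus.bedgraph", d / f"{lib}_minus.bedgraph"
        if plus.is_file() and minus.is_file():
            tracks += gio.read_bedgraph_pair(plus, minus, lib, model)
    clusters = []
    if (d / "clusters.bed").is_file():
        clusters = [
            (name, start, end) for (_, start, end, name) in gio.read_bed(d / "clusters.bed")
        ]
    return SpeciesData(sp.label, model, TrackSet(tracks), clusters)


def run_pipeline(
    config: RunConfig,
    data: dict[str, SpeciesData] | None = None,
    write: bool = True,
) -> PipelineResult:
    """Execute all stages (minus ``config.skip``) and emit the report bundle."""
    logging.basicConfig(
        stream=sys.stderr, level=logging.INFO, format="[%(levelname)s %(name)s] %(message)s"
    )
    for stage in config.skip:
        if stage not in STAGES[1:]:
            raise ValidationError(f"unknown or unskippable stage {stage!r}")
    if data is None:
        data = {sp.label: load_species_data(sp) for sp in config.species}
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    result = PipelineResult(config, {sp.label: SpeciesResult() for sp in config.species})
    seqs_by_species: dict[str, dict[str, str]] = {}
    srna_ids: dict[str, list[str]] = {}

    for sp in config.species:
        d = data[sp.label]
        r = result.species[sp.label]
        sp_out = out / sp.label
        if write:
            sp_out.mkdir(exist_ok=True)

        # -- coverage
        log.info("[%s coverage] computing per-gene MEVs (long library)", sp.label)
        r.thresholds = ThresholdSet(sp.label, sp.t_mev, sp.t_peak)
        r.stats = compute_gene_stats(d.model, d.tracks, "long")
        r.flagged = flag_antisense_candidates(r.stats, r.thresholds)
        log.info("[%s coverage] %d/%d genes flagged", sp.label, len(r.flagged), len(r.stats))
        if write:
            stats_table(r.stats, r.thresholds).to_csv(
                sp_out / "gene_stats.tsv", sep="\t", index=False
            )

        # -- antisense
        if "antisense" not in config.skip:
            rt = dataclasses.replace(config.readthrough, t_rt=sp.t_mev)
            r.primary_calls, r.pair_calls, r.extents = classify_antisense(
                d.model, d.tracks, r.flagged, rt
            )
            log.info(
                "[%s antisense] %d primary calls (%d pair-evidence calls)",
                sp.label, len(r.primary_calls), len(r.pair_calls),
            )
            if write:
                calls_to_dataframe(r.primary_calls).to_csv(
                    sp_out / "antisense_calls.tsv", sep="\t", index=False
                )
                calls_to_gff3(r.primary_calls, sp_out / "antisense_calls.gff3")
                calls_to_dataframe(r.pair_calls).to_csv(
                    sp_out / "antisense_pair_evidence.tsv", sep="\t", index=False
                )

        # -- sRNA
        if "srna" not in config.skip:
            r.srnas, r.companions = call_srnas(d.model, d.tracks, config.srna, sp.prefix)
            log.info(
                "[%s srna] %d sRNAs, %d UTR/rejected islands",
                sp.label, len(r.srnas), len(r.companions),
            )
            if write:
                srnas_to_dataframe(r.srnas).to_csv(
                    sp_out / "srnas.tsv", sep="\t", index=False
                )
                srnas_to_gff3(r.srnas, sp_out / "srnas.gff3")
                srnas_to_dataframe(r.companions).to_csv(
                    sp_out / "srna_companions.tsv", sep="\t", index=False
                )
            srna_ids[sp.label] = [c.name for c in r.srnas]
            try:
                seqs_by_species[sp.label] = {
                    c.name: _call_sequence(d.model, c) for c in r.srnas
                }
            except ValidationError:
                seqs_by_species[sp.label] = {}

        # -- stable fragments
        if "stable" not in config.skip and "short" in d.tracks.libraries():
            r.regions = detect_stable_regions(d.model, d.tracks, config.fragments)
            top = rank_stable_regions(r.regions, k=20)
            log.info("[%s stable] %d regions (top %d ranked)", sp.label, len(r.regions), len(top))
            if write:
                stats = None
                try:
                    usage = codon_usage_table(d.model)
                    stats = [content_analysis(x, d.model, usage) for x in r.regions]
                except ValidationError:
                    pass  # no genome sequence loaded
                regions_to_dataframe(r.regions, stats).to_csv(
                    sp_out / "stable_regions.tsv", sep="\t", index=False
                )

    # -- conservation (cross-species)
    if "conservation" not in config.skip and "srna" not in config.skip:
        log.info("[conservation] aligning %d sRNA sets", len(seqs_by_species))
        if all(seqs_by_species.values()):
            result.links, result.hits = links_from_alignment(
                seqs_by_species,
                min_pident=config.conservation.min_pident,
                min_aln_len=config.conservation.min_aln_len,
                min_score=config.conservation.min_score,
                reciprocal=config.conservation.reciprocal,
            )
            result.conserved_in = build_homology_sets(srna_ids, result.links)
            result.venn = venn_counts(srna_ids, result.conserved_in)
            for sp in config.species:
                d = data[sp.label]
                if d.model.compartments:
                    summary = compartment_summary(
                        result.species[sp.label].srnas, d.model, result.conserved_in
                    )
                    result.summaries[sp.label] = summary
                    if write:
                        summary.to_dataframe().to_csv(
                            out / sp.label / "conservation_summary.tsv",
                            sep="\t", index=False,
                        )
            if write:
                _write_hits(result.hits, out / "homology_hits.tsv")
                _write_venn(result.venn, out / "venn_counts.tsv")

    # -- cluster report
    if "report" not in config.skip and "antisense" not in config.skip:
        for sp in config.species:
            d, r = data[sp.label], result.species[sp.label]
            rid = next(iter(d.model.replicons))
            rows = [(cid, rid, s, e) for cid, s, e in d.clusters]
            r.cluster_annotations, r.cluster_antisense_fraction = annotate_clusters(
                r.primary_calls, rows
            )
            log.info(
                "[%s report] %.0f%% of clusters carry antisense calls",
                sp.label, 100 * (r.cluster_antisense_fraction or 0.0),
            )
            if write and rows:
                clusters_to_dataframe(r.cluster_annotations).to_csv(
                    out / sp.label / "cluster_annotation.tsv", sep="\t", index=False
                )

    if write:
        inputs = [
            Path(sp.fixture_dir) / name
            for sp in config.species
            if sp.fixture_dir
            for name in ("annotation.gff3", "genome.fna")
        ]
        write_manifest(config, out / "manifest.yaml", inputs)
    return result


def _call_sequence(model: GenomeModel, call: SrnaCall) -> str:
    seq = model.sequence(call.replicon_id)[call.start : call.end]
    if call.strand == "-":
        seq = seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
    return seq


def _write_hits(hits: list[HomologyHit], path: Path) -> None:
    df = pd.DataFrame(
        [
            {
                "qseqid": h.query_id,
                "sseqid": h.subject_id,
                "pident": h.percent_identity,
                "length": h.alignment_length,
                "mismatch": 0, "gapopen": 0,
                "qstart": 0, "qend": 0, "sstart": 0, "send": 0,
                "evalue": h.e_value, "bitscore": 0.0,
            }
            for h in hits
        ],
        columns=gio.BLAST_COLUMNS,
    )
    gio.write_blast_tab(df, path)


def _write_venn(venn: dict, path: Path) -> None:
    rows = [
        {"species": sp, "shared_with": ",".join(sorted(pattern)), "n": n}
        for (sp, pattern), n in sorted(
            venn.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1]))
        )
    ]
    pd.DataFrame(rows, columns=["species", "shared_with", "n"]).to_csv(
        path, sep="\t", index=False
    )
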