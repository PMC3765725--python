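"""Readers and writers for the standard formats the pipeline touches.

GFF3 (annotation, 1-based inclusive), bedGraph (per-base stranded coverage,
0-based half-open), FASTA (genome sequence, via Biopython), SAM/BAM
(optional coverage source, via pysam), BED (compartment and cluster
intervals) and the 12-column BLAST tabular dialect (via pandas).

Round-trips are bit-exact on the fields the data model carries; everything
else in an input file is ignored, never mangled.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    FEATURE_CLASSES,
    STRANDS,
    GeneRecord,
    GenomeModel,
    ParseError,
    Replicon,
    StrandedTrack,
    TrackSet,
    ValidationError,
)

log = logging.getLogger(__name__)

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path) -> GenomeModel:
    """Read gene annotation from GFF3 into a GenomeModel.

    Coordinates are converted from 1-based inclusive to internal 0-based
    half-open.  Replicon lengths come from ``##sequence-region`` pragmas;
    replicons mentioned only by features get the maximal feature end as a
    provisional length.  The feature class is taken from a ``gene_biotype``
    attribute when present (default ``protein_coding``).
    """
    path = Path(path)
    replicons: dict[str, Replicon] = {}
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise ParseError(f"{path}:{lineno}: malformed sequence-region pragma")
                rid, _start, end = parts[1], parts[2], parts[3]
                replicons[rid] = Replicon(rid, int(end))
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            rid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise ValidationError(f"{path}:{lineno}: end < start")
            if strand not in STRANDS:
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if ftype not in ("gene",):
                continue
            attr_map = _parse_attributes(attrs, path, lineno)
            gene_id = attr_map.get("ID")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: gene feature without ID attribute")
            fclass = attr_map.get("gene_biotype", "protein_coding")
            if fclass not in FEATURE_CLASSES:
                raise ParseError(f"{path}:{lineno}: unknown gene_biotype {fclass!r}")
            genes.append(
                GeneRecord(gene_id, rid, start1 - 1, end1, strand, fclass)
            )
    for g in genes:
        if g.replicon_id not in replicons:
            replicons[g.replicon_id] = Replicon(g.replicon_id, g.end)
        elif g.end > replicons[g.replicon_id].length:
            replicons[g.replicon_id] = Replicon(g.replicon_id, g.end)
    return GenomeModel(replicons=replicons, genes=genes)


def _parse_attributes(attrs: str, path: Path, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ParseError(f"{path}:{lineno}: malformed attribute {item!r}")
        k, v = item.split("=", 1)
        out[k] = v
    return out


def write_gff3(model: GenomeModel, path: str | Path, source: str = "strepnc") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rid, rep in model.replicons.items():
            fh.write(f"##sequence-region {rid} 1 {rep.length}\n")
        for g in model.genes:
            attrs = f"ID={g.gene_id};gene_biotype={g.feature_class}"
            fh.write(
                f"{g.replicon_id}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path: str | Path, model: GenomeModel) -> dict[str, np.ndarray]:
    """Read one bedGraph file into dense per-base arrays keyed by replicon.

    bedGraph intervals are 0-based half-open; positions absent from the file
    have depth 0.  Values must be non-negative integers (fractional values
    are rejected: tracks are read counts).
    """
    path = Path(path)
    arrays = {
        rid: np.zeros(rep.length, dtype=np.int64)
        for rid, rep in model.replicons.items()
    }
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            rid, start_s, end_s, value_s = fields
            if rid not in arrays:
                raise ValidationError(f"{path}:{lineno}: unknown replicon {rid!r}")
            start, end = int(start_s), int(end_s)
            value = float(value_s)
            if value < 0:
                raise ValidationError(f"{path}:{lineno}: negative value {value}")
            if value != int(value):
                raise ValidationError(f"{path}:{lineno}: non-integer depth {value}")
            if start < 0 or end > arrays[rid].size or end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: interval [{start},{end}) outside replicon "
                    f"of length {arrays[rid].size}"
                )
            arrays[rid][start:end] = int(value)
    return arrays


def read_bedgraph_pair(
    plus_path: str | Path,
    minus_path: str | Path,
    library: str,
    model: GenomeModel,
) -> list[StrandedTrack]:
    """Read a plus/minus bedGraph pair for one library into StrandedTracks."""
    tracks = []
    for strand, p in (("+", plus_path), ("-", minus_path)):
        arrays = read_bedgraph(p, model)
        for rid, depth in arrays.items():
            tracks.append(StrandedTrack(rid, strand, library, depth))
    return tracks


def write_bedgraph(track: StrandedTrack, path: str | Path) -> None:
    """Write a track as run-length-condensed bedGraph (zero runs omitted)."""
    depth = track.depth
    with open(path, "w") as fh:
        if depth.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [depth.size]))
        for s, e in zip(starts, ends):
            v = depth[s]
            if v != 0:
                fh.write(f"{track.replicon_id}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, model: GenomeModel | None = None) -> dict[str, str]:
    """Read sequences; if a model is given, attach them to its replicons."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if model is not None:
        for rid, seq in seqs.items():
            if rid in model.replicons:
                rep = model.replicons[rid]
                if len(seq) != rep.length:
                    raise ValidationError(
                        f"sequence for {rid} has length {len(seq)}, "
                        f"annotation says {rep.length}"
                    )
                rep.sequence = seq
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=rid, description="") for rid, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# SAM/BAM pileup

def depth_from_alignments(
    alignment_path: str | Path, model: GenomeModel, library: str = "long"
) -> list[StrandedTrack]:
    """Per-base, per-strand depth from a coordinate-sorted SAM/BAM file.

    Depth at a position is the number of alignments whose reference span
    covers it (aligned blocks; insertions/clips contribute nothing).  Strand
    comes from the FLAG.  Every reported alignment is counted, including
    secondary alignments of multi-mapped reads.  Unmapped records are
    skipped with a logged count.
    """
    import pysam

    path = str(alignment_path)
    mode = "rb" if path.endswith(".bam") else "r"
    arrays = {
        (rid, s): np.zeros(rep.length, dtype=np.int64)
        for rid, rep in model.replicons.items()
        for s in STRANDS
    }
    n_unmapped = 0
    last_pos: dict[str, int] = {}
    with pysam.AlignmentFile(path, mode) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                n_unmapped += 1
                continue
            rid = aln.reference_name
            if rid not in model.replicons:
                raise ValidationError(f"alignment on unknown replicon {rid!r}")
            if aln.reference_start < last_pos.get(rid, 0):
                raise ValidationError(
                    "input alignments are not coordinate-sorted; "
                    "sort them (e.g. `samtools sort`) and retry"
                )
            last_pos[rid] = aln.reference_start
            strand = "-" if aln.is_reverse else "+"
            arr = arrays[(rid, strand)]
            for block_start, block_end in aln.get_blocks():
                arr[block_start:block_end] += 1
    if n_unmapped:
        log.info("skipped %d unmapped records in %s", n_unmapped, path)
    return [
        StrandedTrack(rid, s, library, depth) for (rid, s), depth in arrays.items()
    ]


# ---------------------------------------------------------------------------
# BED intervals (compartments, clusters)

def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read (replicon, start, end, name) rows from a BED file."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            name = fields[3] if len(fields) > 3 else f"interval_{lineno}"
            rows.append((fields[0], int(fields[1]), int(fields[2]), name))
    return rows


def write_bed(rows: list[tuple[str, int, int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, start, end, name in rows:
            fh.write(f"{rid}\t{start}\t{end}\t{name}\n")


def compartments_from_bed(
    path: str | Path, model: GenomeModel
) -> dict[str, list[tuple[str, int, int]]]:
    comps: dict[str, list[tuple[str, int, int]]] = {}
    for rid, start, end, name in read_bed(path):
        if rid not in model.replicons:
            raise ValidationError(f"compartment on unknown replicon {rid!r}")
        comps.setdefault(rid, []).append((name, start, end))
    for rid in comps:
        comps[rid].sort(key=lambda r: r[1])
    return comps


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

def read_blast_tab(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=BLAST_COLUMNS, comment="#")
    return df


def write_blast_tab(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BLAST_COLUMNS)
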