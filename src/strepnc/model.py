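"""Core data model for annotated replicons and stranded coverage.

All coordinates inside the package are 0-based half-open ``[start, end)``;
format readers/writers convert at the boundary (GFF3 is 1-based inclusive,
bedGraph is already half-open).  Strand is always ``"+"`` or ``"-"``.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-")
FEATURE_CLASSES = ("protein_coding", "rRNA", "tRNA", "ncRNA")
LIBRARIES = ("long", "short")

_TRAILING_DIGITS = re.compile(r"(\d+)$")


class ValidationError(ValueError):
    """An object violates a structural invariant (bad interval, strand, ...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


def opposite(strand: str) -> str:
    if strand not in STRANDS:
        raise ValidationError(f"unknown strand {strand!r}")
    return "-" if strand == "+" else "+"


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene on a replicon.

    ``locus_number`` is parsed from the maximal trailing digit run of
    ``gene_id`` (1434 from ``SCO1434``); genes without trailing digits carry
    ``None`` and are excluded from flank-based sRNA naming.
    """

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    feature_class: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValidationError(
                f"gene {self.gene_id}: unknown feature class {self.feature_class!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def locus_digits(self) -> str | None:
        m = _TRAILING_DIGITS.search(self.gene_id)
        return m.group(1) if m else None

    @property
    def locus_number(self) -> int | None:
        d = self.locus_digits
        return int(d) if d is not None else None

    @property
    def five_prime(self) -> int:
        """Position of the 5' boundary (transcript orientation)."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class Replicon:
    replicon_id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"replicon {self.replicon_id}: length must be > 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"replicon {self.replicon_id}: sequence length "
                f"{len(self.sequence)} != declared length {self.length}"
            )


@dataclass
class GenomeModel:
    """Annotated replicon set: the positional backbone for all interval logic.

    ``compartments`` optionally partitions each replicon into labelled
    intervals (chromosome arm/core regions); when present they must be
    non-overlapping and cover every position queried through
    :meth:`compartment_of`.
    """

    replicons: dict[str, Replicon]
    genes: list[GeneRecord]
    compartments: dict[str, list[tuple[str, int, int]]] | None = None
    _by_id: dict[str, GeneRecord] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.replicon_id, g.start, g.end))
        self._by_id = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            self._by_id[g.gene_id] = g
        self.validate()

    def validate(self) -> None:
        for g in self.genes:
            rep = self.replicons.get(g.replicon_id)
            if rep is None:
                raise ValidationError(
                    f"gene {g.gene_id} on unknown replicon {g.replicon_id!r}"
                )
            if g.end > rep.length:
                raise ValidationError(
                    f"gene {g.gene_id} interval [{g.start},{g.end}) exceeds "
                    f"replicon length {rep.length}"
                )
        if self.compartments is not None:
            for rid, rows in self.compartments.items():
                rows = sorted(rows, key=lambda r: r[1])
                for (_, a0, a1), (_, b0, b1) in zip(rows, rows[1:]):
                    if b0 < a1:
                        raise ValidationError(
                            f"overlapping compartments on {rid}: "
                            f"[{a0},{a1}) and [{b0},{b1})"
                        )

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def genes_on(self, replicon_id: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.replicon_id == replicon_id]

    def gene_mask(self, replicon_id: str) -> np.ndarray:
        """Boolean per-base mask: True where any gene (either strand) lies."""
        rep = self.replicons[replicon_id]
        mask = np.zeros(rep.length, dtype=bool)
        for g in self.genes_on(replicon_id):
            mask[g.start : g.end] = True
        return mask

    def genes_overlapping(
        self, replicon_id: str, start: int, end: int, strand: str | None = None
    ) -> list[GeneRecord]:
        out = []
        for g in self.genes_on(replicon_id):
            if g.overlaps(start, end) and (strand is None or g.strand == strand):
                out.append(g)
        return out

    def compartment_of(self, replicon_id: str, pos: int) -> str:
        if self.compartments is None or replicon_id not in self.compartments:
            raise ValidationError(f"no compartments defined for {replicon_id!r}")
        for label, start, end in self.compartments[replicon_id]:
            if start <= pos < end:
                return label
        raise ValidationError(
            f"position {pos} on {replicon_id} falls outside every compartment"
        )

    def sequence(self, replicon_id: str) -> str:
        seq = self.replicons[replicon_id].sequence
        if seq is None:
            raise ValidationError(f"no sequence loaded for replicon {replicon_id!r}")
        return seq


@dataclass
class StrandedTrack:
    """Dense per-base integer depth for one strand / library / replicon."""

    replicon_id: str
    strand: str
    library: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.library not in LIBRARIES:
            raise ValidationError(f"bad library {self.library!r}")
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValidationError("depth must be one-dimensional")
        if (self.depth < 0).any():
            raise ValidationError("negative depth values")


class TrackSet:
    """Lookup of StrandedTracks keyed by (replicon, strand, library)."""

    def __init__(self, tracks: list[StrandedTrack]):
        self._d: dict[tuple[str, str, str], StrandedTrack] = {}
        for t in tracks:
            key = (t.replicon_id, t.strand, t.library)
            if key in self._d:
                raise ValidationError(f"duplicate track {key}")
            self._d[key] = t

    def track(self, replicon_id: str, strand: str, library: str) -> StrandedTrack:
        try:
            return self._d[(replicon_id, strand, library)]
        except KeyError:
            raise KeyError(
                f"no track for replicon={replicon_id!r} strand={strand!r} "
                f"library={library!r}"
            ) from None

    def depth(self, replicon_id: str, strand: str, library: str) -> np.ndarray:
        return self.track(replicon_id, strand, library).depth

    def tracks(self) -> list[StrandedTrack]:
        return list(self._d.values())

    def libraries(self) -> set[str]:
        return {lib for (_, _, lib) in self._d}

    def covers(self, model: GenomeModel, library: str) -> bool:
        return all(
            (rid, s, library) in self._d
            for rid in model.replicons
            for s in STRANDS
        )
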