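"""Classification of antisense transcription into asRNA / cutoRNA /
divergent-overlap / unclassified calls.

The classifier works from genomic context plus coverage continuity in the
long-transcript library:

* a gene's transcribed extent is measured by scanning outward from its
  annotated boundaries while depth stays above a continuity floor
  (sub-floor gaps up to a few nt are bridged);
* a 3' extent that runs into a convergently oriented, opposite-strand gene
  by at least ``o_min`` nt is a cutoRNA (convergent untranslated
  overlapping RNA) — read-through may traverse whole genes, and each
  traversed opposite-strand gene gets its own call;
* overlapping 5' extents of a divergent gene pair are a divergent-overlap;
* an antisense island not explained by either mechanism but with a sharp
  5' boundary is an independently promoted asRNA; everything else is
  unclassified.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import islands, overlap_length
from .model import GenomeModel, GeneRecord, TrackSet, ValidationError, opposite

CATEGORIES = ("asRNA", "cutoRNA", "divergent_overlap", "unclassified")


@dataclass(frozen=True)
class ReadthroughParams:
    """Continuity and classification parameters.

    The source study judged these by eye in a genome browser; here they are
    explicit and recorded in the run manifest.  ``t_rt`` defaults to the
    species MEV threshold.
    """

    t_rt: float = 10.0          # continuity floor, reads per base
    gap_tolerance: int = 5      # nt of sub-floor signal bridged
    o_min: int = 50             # minimum 3' overlap for a cutoRNA call, nt
    explained_min: float = 0.8  # fraction of island mass a partner must explain
    beta: float = 0.2           # sharp-start depth fraction
    sharp_window: int = 25      # nt within which the 5' rise must occur
    island_floor: float | None = None  # antisense island floor; default t_rt

    @property
    def floor(self) -> float:
        return self.t_rt if self.island_floor is None else self.island_floor


@dataclass(frozen=True)
class TranscribedExtent:
    """Continuous transcribed extents flanking one gene on its own strand.

    ``utr5``/``utr3`` are absolute [start, end) intervals abutting the gene
    boundaries, or None when coverage stops immediately.
    """

    gene_id: str
    strand: str
    utr5: tuple[int, int] | None
    utr3: tuple[int, int] | None
    t_rt: float
    gap_tolerance: int


@dataclass(frozen=True)
class AntisenseCall:
    gene_id: str
    replicon_id: str
    category: str
    start: int
    end: int
    strand: str                       # strand of the antisense signal
    partner_gene_id: str | None = None
    overlap_length: int | None = None
    mev_antisense: float | None = None
    peak_antisense: int | None = None
    explained_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown antisense category {self.category!r}")


def _scan(depth: np.ndarray, start: int, step: int, floor: float, gap: int) -> int | None:
    """Furthest position with depth >= floor reachable from ``start`` moving
    by ``step``, bridging sub-floor runs of at most ``gap`` nt."""
    n = depth.size
    last_good = None
    gap_run = 0
    p = start
    while 0 <= p < n:
        if depth[p] >= floor:
            last_good = p
            gap_run = 0
        else:
            gap_run += 1
            if gap_run > gap:
                break
        p += step
    return last_good


def measure_readthrough(
    model: GenomeModel,
    tracks: TrackSet,
    gene_id: str,
    params: ReadthroughParams,
    library: str = "long",
) -> TranscribedExtent:
    """Measure 5'/3' transcribed extents of one gene on its own strand."""
    g = model.gene(gene_id)
    depth = tracks.depth(g.replicon_id, g.strand, library)
    if g.strand == "+":
        up_last = _scan(depth, g.start - 1, -1, params.t_rt, params.gap_tolerance)
        down_last = _scan(depth, g.end, +1, params.t_rt, params.gap_tolerance)
        utr5 = (up_last, g.start) if up_last is not None else None
        utr3 = (g.end, down_last + 1) if down_last is not None else None
    else:
        up_last = _scan(depth, g.end, +1, params.t_rt, params.gap_tolerance)
        down_last = _scan(depth, g.start - 1, -1, params.t_rt, params.gap_tolerance)
        utr5 = (g.end, up_last + 1) if up_last is not None else None
        utr3 = (down_last, g.start) if down_last is not None else None
    return TranscribedExtent(
        gene_id, g.strand, utr5, utr3, params.t_rt, params.gap_tolerance
    )


def compute_extents(
    model: GenomeModel,
    tracks: TrackSet,
    params: ReadthroughParams,
    library: str = "long",
) -> dict[str, TranscribedExtent]:
    return {
        g.gene_id: measure_readthrough(model, tracks, g.gene_id, params, library)
        for g in model.genes
    }


def _is_downstream(g: GeneRecord, p: GeneRecord) -> bool:
    """True when ``p`` lies downstream of ``g`` in g's transcription sense."""
    return p.start >= g.end if g.strand == "+" else p.end <= g.start


def detect_cutorna_pairs(
    model: GenomeModel,
    extents: dict[str, TranscribedExtent],
    params: ReadthroughParams,
) -> list[AntisenseCall]:
    """cutoRNA calls: one per opposite-strand gene overlapped >= o_min nt by
    a 3' read-through extent.  Reciprocal read-through yields one call per
    direction; tandem and divergent neighbours can never qualify because a
    3' extent only reaches downstream, opposite-strand genes."""
    calls = []
    for g in model.genes:
        ext = extents.get(g.gene_id)
        if ext is None or ext.utr3 is None:
            continue
        for p in model.genes_overlapping(
            g.replicon_id, ext.utr3[0], ext.utr3[1], strand=opposite(g.strand)
        ):
            if not _is_downstream(g, p):
                continue
            ov = overlap_length(ext.utr3, (p.start, p.end))
            if ov < params.o_min:
                continue
            s = max(ext.utr3[0], p.start)
            e = min(ext.utr3[1], p.end)
            calls.append(
                AntisenseCall(
                    gene_id=p.gene_id,
                    replicon_id=p.replicon_id,
                    category="cutoRNA",
                    start=s,
                    end=e,
                    strand=g.strand,
                    partner_gene_id=g.gene_id,
                    overlap_length=ov,
                )
            )
    return calls


def detect_divergent_overlap(
    model: GenomeModel,
    extents: dict[str, TranscribedExtent],
    params: ReadthroughParams,
) -> list[AntisenseCall]:
    """Divergent-overlap calls for adjacent head-to-head gene pairs whose 5'
    extents intersect (or whose 5' extent reaches the partner's body)."""
    calls = []
    by_replicon: dict[str, list[GeneRecord]] = {}
    for g in model.genes:
        by_replicon.setdefault(g.replicon_id, []).append(g)
    for rid, genes in by_replicon.items():
        for a, b in zip(genes, genes[1:]):
            if not (a.strand == "-" and b.strand == "+"):
                continue  # not a divergent pair (a points left, b points right)
            ea, eb = extents.get(a.gene_id), extents.get(b.gene_id)
            ua = ea.utr5 if ea else None
            ub = eb.utr5 if eb else None
            touching = (
                (ua and ub and overlap_length(ua, ub) >= 1)
                or (ua and overlap_length(ua, (b.start, b.end)) >= 1)
                or (ub and overlap_length(ub, (a.start, a.end)) >= 1)
            )
            if not touching:
                continue
            for gene, partner, partner_utr5 in ((a, b, ub), (b, a, ua)):
                if partner_utr5 is None:
                    continue
                body = (
                    max(partner_utr5[0], gene.start),
                    min(partner_utr5[1], gene.end),
                )
                if body[1] <= body[0]:
                    # partner 5' extent stays intergenic; report the extent
                    # overlap region itself
                    other = ua if gene is a else ub
                    if other is None:
                        continue
                    body = (
                        max(partner_utr5[0], other[0]),
                        min(partner_utr5[1], other[1]),
                    )
                    if body[1] <= body[0]:
                        continue
                calls.append(
                    AntisenseCall(
                        gene_id=gene.gene_id,
                        replicon_id=rid,
                        category="divergent_overlap",
                        start=body[0],
                        end=body[1],
                        strand=partner.strand,
                        partner_gene_id=partner.gene_id,
                        overlap_length=body[1] - body[0],
                    )
                )
    return calls


def _partner_extents_for(
    model: GenomeModel,
    g: GeneRecord,
    extents: dict[str, TranscribedExtent],
) -> tuple[list[tuple[str, tuple[int, int]]], list[tuple[str, tuple[int, int]]]]:
    """Opposite-strand partner extents overlapping gene ``g``: (cuto, div).

    cuto sources are convergent partners whose 3' extent reaches into g;
    div sources are divergent partners whose 5' extent reaches into g.
    """
    anti = opposite(g.strand)
    cuto, div = [], []
    for p in model.genes_on(g.replicon_id):
        if p.strand != anti or p.gene_id == g.gene_id:
            continue
        ext = extents.get(p.gene_id)
        if ext is None:
            continue
        if ext.utr3 and _is_downstream(p, g) and overlap_length(
            ext.utr3, (g.start, g.end)
        ) >= 1:
            cuto.append((p.gene_id, ext.utr3))
        if ext.utr5 and overlap_length(ext.utr5, (g.start, g.end)) >= 1:
            # 5' extents reach upstream of p; an overlap with g means the
            # pair is divergent (g upstream of p on the opposite strand).
            if not _is_downstream(p, g):
                div.append((p.gene_id, ext.utr5))
    return cuto, div


def _island_mass_in(
    depth: np.ndarray, island: tuple[int, int], interval: tuple[int, int], offset: int
) -> int:
    s = max(island[0], interval[0]) - offset
    e = min(island[1], interval[1]) - offset
    if e <= s:
        return 0
    return int(depth[s:e].sum())


def classify_gene(
    model: GenomeModel,
    tracks: TrackSet,
    gene_id: str,
    flagged: bool,
    extents: dict[str, TranscribedExtent],
    params: ReadthroughParams,
    library: str = "long",
) -> list[AntisenseCall]:
    """Primary antisense calls for one flagged gene, one per antisense island.

    Islands are segmented first; each island is explained against partner
    read-through / divergent 5' extents, falling back to the sharp-start
    test for an independently promoted asRNA, and to ``unclassified`` when
    no rule fires.
    """
    if not flagged:
        raise ValidationError(
            f"classify_gene contract: {gene_id} was not flagged as a candidate"
        )
    g = model.gene(gene_id)
    anti_strand = opposite(g.strand)
    depth_full = tracks.depth(g.replicon_id, anti_strand, library)
    seg = depth_full[g.start : g.end]
    isl = islands(seg, params.floor, params.gap_tolerance)
    cuto_src, div_src = _partner_extents_for(model, g, extents)
    calls = []
    for s_rel, e_rel in isl:
        island_abs = (g.start + s_rel, g.start + e_rel)
        island_depth = seg[s_rel:e_rel]
        mass = int(island_depth.sum())
        if mass == 0:
            continue
        best_cuto = max(
            (
                ( _island_mass_in(seg, island_abs, ext, g.start), pid)
                for pid, ext in cuto_src
            ),
            default=(0, None),
        )
        best_div = max(
            (
                ( _island_mass_in(seg, island_abs, ext, g.start), pid)
                for pid, ext in div_src
            ),
            default=(0, None),
        )
        explained_mask = np.zeros(e_rel - s_rel, dtype=bool)
        for _, ext in cuto_src + div_src:
            lo = max(ext[0], island_abs[0]) - island_abs[0]
            hi = min(ext[1], island_abs[1]) - island_abs[0]
            if hi > lo:
                explained_mask[lo:hi] = True
        explained = int(island_depth[explained_mask].sum())
        frac = explained / mass
        mev = mass / (e_rel - s_rel)
        peak = int(island_depth.max())
        if frac >= params.explained_min and (best_cuto[0] > 0 or best_div[0] > 0):
            if best_cuto[0] >= best_div[0]:
                category, partner = "cutoRNA", best_cuto[1]
            else:
                category, partner = "divergent_overlap", best_div[1]
        elif _sharp_start(depth_full, island_abs, anti_strand, params):
            category, partner = "asRNA", None
        else:
            category, partner = "unclassified", None
        calls.append(
            AntisenseCall(
                gene_id=gene_id,
                replicon_id=g.replicon_id,
                category=category,
                start=island_abs[0],
                end=island_abs[1],
                strand=anti_strand,
                partner_gene_id=partner,
                overlap_length=None,
                mev_antisense=mev,
                peak_antisense=peak,
                explained_fraction=frac,
            )
        )
    return calls


def _sharp_start(
    depth: np.ndarray, island: tuple[int, int], strand: str, params: ReadthroughParams
) -> bool:
    """Sharp 5' boundary test: depth just outside the island's 5' edge stays
    below beta*max while within ``sharp_window`` nt inside it reaches
    beta*max — the signature of a dedicated promoter rather than diffuse
    read-through."""
    s, e = island
    m = float(depth[s:e].max())
    if m <= 0:
        return False
    w = params.sharp_window
    thr = params.beta * m
    if strand == "+":
        outside = depth[max(0, s - w) : s]
        inside = depth[s : min(e, s + w)]
    else:
        outside = depth[e : e + w]
        inside = depth[max(s, e - w) : e]
    outside_low = outside.size == 0 or float(outside.mean()) < thr
    inside_high = inside.size > 0 and float(inside.max()) >= thr
    return bool(outside_low and inside_high)


def classify_antisense(
    model: GenomeModel,
    tracks: TrackSet,
    flagged: set[str],
    params: ReadthroughParams,
    library: str = "long",
) -> tuple[list[AntisenseCall], list[AntisenseCall], dict[str, TranscribedExtent]]:
    """Full classification pass.

    Returns (primary per-gene calls for flagged genes, pair-level
    cutoRNA/divergent evidence calls, measured extents).
    """
    extents = compute_extents(model, tracks, params, library)
    pair_calls = detect_cutorna_pairs(model, extents, params)
    pair_calls += detect_divergent_overlap(model, extents, params)
    primary = []
    for gid in sorted(flagged):
        primary.extend(
            classify_gene(model, tracks, gid, True, extents, params, library)
        )
    return primary, pair_calls, extents


# ---------------------------------------------------------------------------
# Output

def calls_to_dataframe(calls: list[AntisenseCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "replicon_id": c.replicon_id,
                "category": c.category,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "partner_gene_id": c.partner_gene_id,
                "overlap_length": c.overlap_length,
                "mev_antisense": c.mev_antisense,
                "peak_antisense": c.peak_antisense,
                "explained_fraction": c.explained_fraction,
            }
            for c in calls
        ]
    )


def calls_to_gff3(calls: list[AntisenseCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls, start=1):
            attrs = [f"ID=antisense{i:05d}", f"gene={c.gene_id}"]
            if c.partner_gene_id:
                attrs.append(f"partner={c.partner_gene_id}")
            if c.overlap_length is not None:
                attrs.append(f"overlap_length={c.overlap_length}")
            fh.write(
                f"{c.replicon_id}\tstrepnc\t{c.category}\t{c.start + 1}\t{c.end}\t.\t"
                f"{c.strand}\t.\t{';'.join(attrs)}\n"
            )
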