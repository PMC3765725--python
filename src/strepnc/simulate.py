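"""Synthetic three-species transcriptome fixtures with planted ncRNAs.

The generator emulates the structure of a strand-specific *Streptomyces*
RNA-seq study: for each simulated species it lays out one annotated
replicon (GC-rich sequence, protein-coding genes with realistic lengths
and intergenic gaps, arm/core compartments, secondary-metabolite-style
gene clusters) and two stranded coverage tracks per strand — a
long-transcript library with even gene-body coverage and a size-selected
short library enriched at UTRs and structured internal elements.

Planted ground truth covers every call class downstream stages emit:

* asRNAs (sharp antisense islands inside genes),
* cutoRNAs (3' read-through of a convergent gene into its opposite-strand
  partner),
* divergent 5'-overlap pairs,
* 40-300 nt intergenic sRNAs, organised into cross-species homolog
  families (point-substituted copies of a family sequence),
* stable short-library regions (5'/3'-end-associated and 30-90 nt
  internal, 100-1000x over the gene-body baseline) plus 50x decoys that
  must never be called.

Per-base depth is negative-binomial around the planted mean (Gamma-Poisson
mixture, mild overdispersion) plus a low Poisson background on both
strands.  Same seed, same output, byte for byte.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    GeneRecord,
    GenomeModel,
    Replicon,
    StrandedTrack,
    TrackSet,
    ValidationError,
    opposite,
)

FEATURE_KINDS = (
    "asRNA",
    "cutoRNA",
    "divergent_overlap",
    "sRNA",
    "stable_region_5p",
    "stable_region_3p",
    "stable_region_internal",
    "stable_decoy",
)

_STABLE_CLASS = {
    "stable_region_5p": "utr5",
    "stable_region_3p": "utr3_or_intergenic_operon",
    "stable_region_internal": "internal",
}


class SimulationError(RuntimeError):
    """Feature packing or configuration is infeasible; never silently truncated."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic fixture.

    Defaults mirror the emulated study where it states values (GC > 0.70,
    40-300 nt sRNAs, 100-1000x short-library enrichment, ~30-90 nt internal
    stable elements, three species); everything else is a realistic choice
    for a streptomycete transcriptome, documented in the methods note.
    """

    seed: int = 0
    species: tuple[str, ...] = ("S1", "S2", "S3")
    srna_prefixes: tuple[str, ...] = ("s1r", "s2r", "s3r")
    n_genes: int = 72
    gene_len_log_mean: float = math.log(800.0)
    gene_len_log_sd: float = 0.35
    gene_len_bounds: tuple[int, int] = (300, 2000)
    intergap_base: int = 80
    intergap_scale: float = 260.0
    intergap_max: int = 1500
    gc_content: float = 0.72
    end_margin: int = 500
    # expression
    gene_depth_log_mean: float = math.log(60.0)
    gene_depth_log_sd: float = 0.5
    gene_depth_bounds: tuple[float, float] = (15.0, 400.0)
    utr5_len: tuple[int, int] = (10, 30)
    utr3_len: tuple[int, int] = (15, 40)
    utr_depth_frac: float = 0.7
    short_body_depth: tuple[float, float] = (2.0, 6.0)
    dispersion: float = 50.0
    background_depth: float = 0.05
    # antisense classes (per species)
    n_asrna: int = 6
    asrna_depth: tuple[float, float] = (30.0, 80.0)
    asrna_len: tuple[int, int] = (100, 250)
    n_cutorna: int = 8
    cuto_depth: tuple[float, float] = (25.0, 60.0)
    cuto_overlap: tuple[int, int] = (100, 300)
    n_divergent: int = 4
    div_depth: tuple[float, float] = (25.0, 60.0)
    div_into_body: tuple[int, int] = (60, 150)
    # sRNAs: homolog families across species + unique per species
    srna_families_all: int = 6
    srna_families_pairs: tuple[tuple[tuple[int, int], int], ...] = (
        ((0, 1), 4), ((0, 2), 2), ((1, 2), 2),
    )
    srna_unique_per_species: int = 6
    srna_len: tuple[int, int] = (40, 300)
    family_len: tuple[int, int] = (80, 280)
    srna_short_depth: tuple[float, float] = (50.0, 500.0)
    srna_long_depth: tuple[float, float] = (20.0, 100.0)
    srna_margin: int = 15
    mutation_rate: float = 0.10
    # stable fragments (per species)
    n_stable_utr5: int = 5
    n_stable_utr3: int = 5
    n_stable_internal: int = 6
    n_stable_decoy: int = 5
    stable_fold: tuple[float, float] = (100.0, 1000.0)  # log-uniform
    decoy_fold: float = 50.0
    stable_len: tuple[int, int] = (30, 90)
    end_zone: int = 25
    # genome furniture
    n_trna: int = 2
    compartment_fracs: tuple[float, ...] = (0.06, 0.16, 0.52, 0.16, 0.10)
    compartment_labels: tuple[str, ...] = (
        "left_terminal",
        "left_actinomycetales",
        "core",
        "right_streptomyces",
        "right_terminal",
    )
    n_clusters: int = 10
    cluster_genes: tuple[int, int] = (3, 6)

    def __post_init__(self) -> None:
        if len(self.species) != len(self.srna_prefixes):
            raise ValidationError("one sRNA prefix per species required")
        if not (1.0 <= self.stable_fold[0] <= self.stable_fold[1] <= 1e4):
            raise ValidationError("enrichment range must lie within [1, 1e4]")
        if abs(sum(self.compartment_fracs) - 1.0) > 1e-9:
            raise ValidationError("compartment fractions must sum to 1")


def null_antisense_config(config: SimConfig) -> SimConfig:
    """Same conditions with no planted antisense of any class."""
    return replace(config, n_asrna=0, n_cutorna=0, n_divergent=0)


@dataclass(frozen=True)
class PlantedFeature:
    feature_id: str
    species: str
    kind: str
    replicon_id: str
    start: int
    end: int
    strand: str
    expression_level: float
    partner_gene_id: str | None = None
    gene_id: str | None = None
    conserved_in: frozenset[str] = frozenset()
    mutation_rate: float = 0.0
    family: str | None = None
    fold: float | None = None
    location_class: str | None = None
    long_depth: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown planted kind {self.kind!r}")
        if self.expression_level <= 0:
            raise ValidationError("expression level must be positive")


@dataclass
class SimResult:
    config: SimConfig
    models: dict[str, GenomeModel]
    tracks: dict[str, TrackSet]
    features: list[PlantedFeature]
    homolog_pairs: pd.DataFrame
    clusters: dict[str, list[tuple[str, int, int]]]

    def features_of(self, species: str, kind: str | None = None) -> list[PlantedFeature]:
        return [
            f for f in self.features
            if f.species == species and (kind is None or f.kind == kind)
        ]


@dataclass
class _Family:
    family_id: str
    members: tuple[int, ...]   # species indices
    length: int
    base_seq: str


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _mutate_exact(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute exactly round(rate * L) distinct random sites."""
    n = int(round(rate * len(seq)))
    if n == 0:
        return seq
    sites = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for i in sites:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _uniform_int(rng, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def _uniform(rng, bounds) -> float:
    return float(rng.uniform(bounds[0], bounds[1]))


def _make_families(config: SimConfig, rng: np.random.Generator) -> list[_Family]:
    plans: list[tuple[int, ...]] = []
    all_idx = tuple(range(len(config.species)))
    plans += [all_idx] * config.srna_families_all
    for pair, n in config.srna_families_pairs:
        plans += [tuple(pair)] * n
    for k in all_idx:
        plans += [(k,)] * config.srna_unique_per_species
    families = []
    for i, members in enumerate(plans):
        bounds = config.family_len if len(members) > 1 else config.srna_len
        length = _uniform_int(rng, *bounds)
        families.append(
            _Family(f"fam{i:03d}", members, length, _random_seq(rng, length, config.gc_content))
        )
    return families


def simulate_species_set(config: SimConfig) -> SimResult:
    """Generate the full multi-species fixture.

    Deterministic under ``config.seed``; raises :class:`SimulationError`
    when the requested features cannot be packed into the genome layout.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.species) + 1)
    master = np.random.default_rng(children[0])
    families = _make_families(config, master)

    models: dict[str, GenomeModel] = {}
    tracksets: dict[str, TrackSet] = {}
    clusters: dict[str, list[tuple[str, int, int]]] = {}
    features: list[PlantedFeature] = []
    srna_ids_by_family: dict[str, list[tuple[str, str]]] = {}

    for k, sp in enumerate(config.species):
        rng = np.random.default_rng(children[k + 1])
        fam_members = [f for f in families if k in f.members]
        bundle = _build_species(config, k, sp, rng, fam_members)
        models[sp] = bundle["model"]
        tracksets[sp] = bundle["tracks"]
        clusters[sp] = bundle["clusters"]
        features.extend(bundle["features"])
        for fid, fam_id in bundle["family_of"]:
            srna_ids_by_family.setdefault(fam_id, []).append((sp, fid))

    rows = []
    for fam_id, members in sorted(srna_ids_by_family.items()):
        if len(members) < 2:
            continue
        for (sp_a, id_a), (sp_b, id_b) in (
            (m, n) for i, m in enumerate(members) for n in members[i + 1 :]
        ):
            rows.append(
                {"family": fam_id, "species_a": sp_a, "srna_id_a": id_a,
                 "species_b": sp_b, "srna_id_b": id_b}
            )
    homolog_pairs = pd.DataFrame(
        rows, columns=["family", "species_a", "srna_id_a", "species_b", "srna_id_b"]
    )
    return SimResult(config, models, tracksets, features, homolog_pairs, clusters)


def _build_species(
    config: SimConfig,
    k: int,
    sp: str,
    rng: np.random.Generator,
    fam_members: list[_Family],
) -> dict:
    n = config.n_genes
    rid = f"{sp}_chr"

    gene_lens = np.clip(
        np.round(rng.lognormal(config.gene_len_log_mean, config.gene_len_log_sd, n)),
        *config.gene_len_bounds,
    ).astype(int)

    # ---- gap roles -------------------------------------------------------
    n_gaps = n - 1
    srna_lengths = [f.length for f in fam_members]
    order = rng.permutation(n_gaps)
    pair_roles: dict[int, str] = {}
    want_pairs = [("cuto", config.n_cutorna), ("div", config.n_divergent)]
    queue = [role for role, cnt in want_pairs for _ in range(cnt)]
    for idx in order:
        if not queue:
            break
        if any(abs(idx - j) <= 1 for j in pair_roles):
            continue
        pair_roles[int(idx)] = queue.pop(0)
    if queue:
        raise SimulationError(
            f"{sp}: cannot place {len(queue)} convergent/divergent pairs in "
            f"{n_gaps} intergenic gaps"
        )
    free = [int(i) for i in order if int(i) not in pair_roles]
    if len(free) < len(srna_lengths):
        raise SimulationError(
            f"{sp}: {len(srna_lengths)} sRNAs but only {len(free)} free gaps"
        )
    srna_gap: dict[int, _Family] = {
        gap: fam for gap, fam in zip(free, fam_members)
    }

    # ---- gap sizes and coordinates --------------------------------------
    gap_sizes = np.minimum(
        config.intergap_base
        + np.round(rng.exponential(config.intergap_scale, n_gaps)).astype(int),
        config.intergap_max,
    )
    for i, role in pair_roles.items():
        gap_sizes[i] = (
            _uniform_int(rng, 90, 200) if role == "cuto" else _uniform_int(rng, 40, 120)
        )
    for i, fam in srna_gap.items():
        gap_sizes[i] = fam.length + 2 * config.srna_margin + _uniform_int(rng, 0, 150)

    starts = np.empty(n, dtype=int)
    pos = config.end_margin
    for i in range(n):
        starts[i] = pos
        pos += gene_lens[i]
        if i < n_gaps:
            pos += gap_sizes[i]
    ends = starts + gene_lens
    rep_len = int(ends[-1] + config.end_margin)

    # ---- strands ---------------------------------------------------------
    strands = list(rng.choice(["+", "-"], size=n))
    for i, role in pair_roles.items():
        if role == "cuto":
            strands[i], strands[i + 1] = "+", "-"
        else:
            strands[i], strands[i + 1] = "-", "+"

    pair_flank = {i for j in pair_roles for i in (j, j + 1)}
    host_pool = [i for i in range(n) if i not in pair_flank]
    rng.shuffle(host_pool)

    trna_idx = set(host_pool[: config.n_trna])
    host_pool = host_pool[config.n_trna :]

    genes = [
        GeneRecord(
            gene_id=f"{sp}G{i + 1:04d}",
            replicon_id=rid,
            start=int(starts[i]),
            end=int(ends[i]),
            strand=strands[i],
            feature_class="tRNA" if i in trna_idx else "protein_coding",
        )
        for i in range(n)
    ]

    # ---- compartments and clusters --------------------------------------
    comp_rows = []
    acc = 0
    for frac, label in zip(config.compartment_fracs, config.compartment_labels):
        width = int(round(frac * rep_len))
        comp_rows.append((label, acc, min(acc + width, rep_len)))
        acc += width
    comp_rows[-1] = (comp_rows[-1][0], comp_rows[-1][1], rep_len)

    cluster_rows: list[tuple[str, int, int]] = []
    used = np.zeros(n, dtype=bool)
    attempts = rng.permutation(n)
    for start_idx in attempts:
        if len(cluster_rows) >= config.n_clusters:
            break
        w = _uniform_int(rng, *config.cluster_genes)
        if start_idx + w > n or used[start_idx : start_idx + w].any():
            continue
        used[start_idx : start_idx + w] = True
        c_start = max(0, int(starts[start_idx]) - 50)
        c_end = min(rep_len, int(ends[start_idx + w - 1]) + 50)
        cluster_rows.append((f"{sp}_cluster{len(cluster_rows) + 1:02d}", c_start, c_end))
    cluster_rows.sort(key=lambda r: r[1])

    model = GenomeModel(
        replicons={rid: Replicon(rid, rep_len)},
        genes=genes,
        compartments={rid: comp_rows},
    )

    # ---- expression ------------------------------------------------------
    mu_long = np.clip(
        rng.lognormal(config.gene_depth_log_mean, config.gene_depth_log_sd, n),
        *config.gene_depth_bounds,
    )
    mu_short = rng.uniform(*config.short_body_depth, size=n)

    mean = {
        (s, lib): np.zeros(rep_len)
        for s in ("+", "-")
        for lib in ("long", "short")
    }
    for i, g in enumerate(genes):
        mean[(g.strand, "long")][g.start : g.end] = mu_long[i]
        mean[(g.strand, "short")][g.start : g.end] = mu_short[i]

    features: list[PlantedFeature] = []
    family_of: list[tuple[str, str]] = []
    counters: dict[str, int] = {}

    def fid(kind: str) -> str:
        counters[kind] = counters.get(kind, 0) + 1
        return f"{sp}_{kind}{counters[kind]:02d}"

    # ---- cutoRNA / divergent pairs --------------------------------------
    div_flank_5p: set[int] = set()
    cuto_a: set[int] = set()
    for j, role in sorted(pair_roles.items()):
        a, b = genes[j], genes[j + 1]
        if role == "cuto":
            o = _uniform_int(
                rng, config.cuto_overlap[0],
                max(config.cuto_overlap[0], min(config.cuto_overlap[1], b.length - 60)),
            )
            depth = _uniform(rng, config.cuto_depth)
            rt = (a.end, b.start + o)
            arr = mean[("+", "long")]
            arr[rt[0] : rt[1]] = np.maximum(arr[rt[0] : rt[1]], depth)
            cuto_a.add(j)
            features.append(
                PlantedFeature(
                    feature_id=fid("cuto"), species=sp, kind="cutoRNA",
                    replicon_id=rid, start=b.start, end=b.start + o, strand="+",
                    expression_level=depth, partner_gene_id=a.gene_id,
                    gene_id=b.gene_id,
                )
            )
        else:
            into_a = _uniform_int(
                rng, config.div_into_body[0],
                max(config.div_into_body[0], min(config.div_into_body[1], b.length - 60)),
            )
            into_b = _uniform_int(
                rng, config.div_into_body[0],
                max(config.div_into_body[0], min(config.div_into_body[1], a.length - 60)),
            )
            d_a = _uniform(rng, config.div_depth)
            d_b = _uniform(rng, config.div_depth)
            arr = mean[("-", "long")]  # a's 5' extension, rightwards into b
            arr[a.end : b.start + into_a] = np.maximum(
                arr[a.end : b.start + into_a], d_a
            )
            arr = mean[("+", "long")]  # b's 5' extension, leftwards into a
            arr[a.end - into_b : b.start] = np.maximum(
                arr[a.end - into_b : b.start], d_b
            )
            div_flank_5p.update((j, j + 1))
            features.append(
                PlantedFeature(
                    feature_id=fid("div"), species=sp, kind="divergent_overlap",
                    replicon_id=rid, start=b.start, end=b.start + into_a,
                    strand="-", expression_level=d_a,
                    partner_gene_id=a.gene_id, gene_id=b.gene_id,
                )
            )
            features.append(
                PlantedFeature(
                    feature_id=fid("div"), species=sp, kind="divergent_overlap",
                    replicon_id=rid, start=a.end - into_b, end=a.end,
                    strand="+", expression_level=d_b,
                    partner_gene_id=b.gene_id, gene_id=a.gene_id,
                )
            )

    # ---- default gene UTR extensions ------------------------------------
    # suppressed on sides that face an sRNA-hosting gap (to keep planted
    # sRNAs discontinuous from gene signal) and replaced by planted
    # extensions on cutoRNA/divergent sides
    for i, g in enumerate(genes):
        left_gap = gap_sizes[i - 1] if i > 0 else config.end_margin
        right_gap = gap_sizes[i] if i < n_gaps else config.end_margin
        left_blocked = (i - 1) in srna_gap if i > 0 else False
        right_blocked = i in srna_gap if i < n_gaps else False
        budget_left = max(0, (left_gap - 14) // 2)
        budget_right = max(0, (right_gap - 14) // 2)
        u5 = _uniform_int(rng, *config.utr5_len)
        u3 = _uniform_int(rng, *config.utr3_len)
        d_utr = config.utr_depth_frac * mu_long[i]
        arr = mean[(g.strand, "long")]
        # 5' side
        if not (i in div_flank_5p):
            if g.strand == "+" and not left_blocked:
                u = min(u5, budget_left)
                arr[g.start - u : g.start] = np.maximum(arr[g.start - u : g.start], d_utr)
            elif g.strand == "-" and not right_blocked:
                u = min(u5, budget_right)
                arr[g.end : g.end + u] = np.maximum(arr[g.end : g.end + u], d_utr)
        # 3' side
        if not (i in cuto_a and g.strand == "+"):
            if g.strand == "+" and not right_blocked:
                u = min(u3, budget_right)
                arr[g.end : g.end + u] = np.maximum(arr[g.end : g.end + u], d_utr)
            elif g.strand == "-" and not left_blocked:
                u = min(u3, budget_left)
                arr[g.start - u : g.start] = np.maximum(arr[g.start - u : g.start], d_utr)

    # ---- asRNAs ----------------------------------------------------------
    as_hosts = [i for i in host_pool if gene_lens[i] >= config.asrna_len[1] + 100]
    if len(as_hosts) < config.n_asrna:
        raise SimulationError(f"{sp}: not enough long genes to host asRNAs")
    as_hosts = as_hosts[: config.n_asrna]
    host_pool = [i for i in host_pool if i not in set(as_hosts)]
    for i in as_hosts:
        g = genes[i]
        length = _uniform_int(rng, *config.asrna_len)
        off = _uniform_int(rng, 25, g.length - length - 25)
        depth = _uniform(rng, config.asrna_depth)
        s0, s1 = g.start + off, g.start + off + length
        anti = opposite(g.strand)
        arr = mean[(anti, "long")]
        arr[s0:s1] = np.maximum(arr[s0:s1], depth)
        features.append(
            PlantedFeature(
                feature_id=fid("as"), species=sp, kind="asRNA", replicon_id=rid,
                start=s0, end=s1, strand=anti, expression_level=depth,
                gene_id=g.gene_id,
            )
        )

    # ---- stable regions and decoys --------------------------------------
    stable_pool = [
        i for i in host_pool
        if gene_lens[i] >= 2 * (config.end_zone + 5) + config.stable_len[1] + 10
    ]
    jobs = (
        [("stable_region_5p", None)] * config.n_stable_utr5
        + [("stable_region_3p", None)] * config.n_stable_utr3
        + [("stable_region_internal", None)] * config.n_stable_internal
        + [("stable_decoy", config.decoy_fold)] * config.n_stable_decoy
    )
    if len(stable_pool) < len(jobs):
        raise SimulationError(f"{sp}: not enough genes to host stable regions")
    for (kind, fixed_fold), i in zip(jobs, stable_pool):
        g = genes[i]
        length = _uniform_int(rng, *config.stable_len)
        if kind == "stable_region_5p":
            s0 = g.start if g.strand == "+" else g.end - length
        elif kind == "stable_region_3p":
            s0 = g.end - length if g.strand == "+" else g.start
        else:
            off = _uniform_int(
                rng, config.end_zone + 5, g.length - length - config.end_zone - 5
            )
            s0 = g.start + off
        s1 = s0 + length
        if fixed_fold is None:
            lo, hi = math.log10(config.stable_fold[0]), math.log10(config.stable_fold[1])
            fold = 10 ** rng.uniform(lo, hi)
        else:
            fold = fixed_fold
        depth = mu_short[i] * fold
        arr = mean[(g.strand, "short")]
        arr[s0:s1] = np.maximum(arr[s0:s1], depth)
        features.append(
            PlantedFeature(
                feature_id=fid("st"), species=sp, kind=kind, replicon_id=rid,
                start=s0, end=s1, strand=g.strand, expression_level=depth,
                gene_id=g.gene_id, fold=fold,
                location_class=_STABLE_CLASS.get(kind),
            )
        )

    # ---- sRNAs -----------------------------------------------------------
    sequence = np.array(list(_random_seq(rng, rep_len, config.gc_content)))
    for gap_idx, fam in sorted(srna_gap.items()):
        gap_start = int(ends[gap_idx])
        gap_len = int(gap_sizes[gap_idx])
        slack = gap_len - fam.length - 2 * config.srna_margin
        off = config.srna_margin + _uniform_int(rng, 0, max(0, slack))
        s0 = gap_start + off
        s1 = s0 + fam.length
        strand = str(rng.choice(["+", "-"]))
        rate = config.mutation_rate if len(fam.members) > 1 else 0.0
        seq = _mutate_exact(rng, fam.base_seq, rate)
        sequence[s0:s1] = list(seq if strand == "+" else _revcomp(seq))
        d_short = _uniform(rng, config.srna_short_depth)
        d_long = _uniform(rng, config.srna_long_depth)
        for lib, d in (("short", d_short), ("long", d_long)):
            arr = mean[(strand, lib)]
            arr[s0:s1] = np.maximum(arr[s0:s1], d)
        conserved = frozenset(
            config.species[m] for m in fam.members if m != k
        )
        feature_id = fid("srna")
        features.append(
            PlantedFeature(
                feature_id=feature_id, species=sp, kind="sRNA", replicon_id=rid,
                start=s0, end=s1, strand=strand, expression_level=d_short,
                conserved_in=conserved, mutation_rate=rate,
                family=fam.family_id if len(fam.members) > 1 else None,
                long_depth=d_long,
            )
        )
        if len(fam.members) > 1:
            family_of.append((feature_id, fam.family_id))

    model.replicons[rid].sequence = "".join(sequence)

    # ---- sample counts ---------------------------------------------------
    tracks = []
    for (strand, lib), m in mean.items():
        lam = np.zeros_like(m)
        positive = m > 0
        lam[positive] = rng.gamma(
            config.dispersion, m[positive] / config.dispersion
        )
        depth = rng.poisson(lam + config.background_depth)
        tracks.append(StrandedTrack(rid, strand, lib, depth))

    return {
        "model": model,
        "tracks": TrackSet(tracks),
        "clusters": cluster_rows,
        "features": features,
        "family_of": family_of,
    }


# ---------------------------------------------------------------------------
# Fixture writing / loading

def write_fixture(result: SimResult, out_dir: str | Path, force: bool = False) -> None:
    """Write the fixture as GFF3 + FASTA + 4 bedGraphs per species plus
    TSV truth tables — exactly the formats the readers consume."""
    from . import io as gio

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    for sp, model in result.models.items():
        d = out / sp
        d.mkdir(exist_ok=True)
        gio.write_gff3(model, d / "annotation.gff3")
        gio.write_fasta(
            {rid: rep.sequence for rid, rep in model.replicons.items()},
            d / "genome.fna",
        )
        ts = result.tracks[sp]
        for lib in ("long", "short"):
            for strand, tag in (("+", "plus"), ("-", "minus")):
                for rid in model.replicons:
                    gio.write_bedgraph(
                        ts.track(rid, strand, lib), d / f"{lib}_{tag}.bedgraph"
                    )
        comp_rows = [
            (rid, s, e, label)
            for rid, rows in (model.compartments or {}).items()
            for (label, s, e) in rows
        ]
        gio.write_bed(comp_rows, d / "compartments.bed")
        rid = next(iter(model.replicons))
        gio.write_bed(
            [(rid, s, e, cid) for cid, s, e in result.clusters[sp]],
            d / "clusters.bed",
        )
    features_to_dataframe(result.features).to_csv(
        out / "planted_features.tsv", sep="\t", index=False
    )
    result.homolog_pairs.to_csv(out / "homolog_pairs.tsv", sep="\t", index=False)


def features_to_dataframe(features: list[PlantedFeature]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": f.feature_id,
                "species": f.species,
                "kind": f.kind,
                "replicon_id": f.replicon_id,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "expression_level": f.expression_level,
                "partner_gene_id": f.partner_gene_id,
                "gene_id": f.gene_id,
                "conserved_in": ",".join(sorted(f.conserved_in)),
                "mutation_rate": f.mutation_rate,
                "family": f.family,
                "fold": f.fold,
                "location_class": f.location_class,
            }
            for f in features
        ]
    )
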