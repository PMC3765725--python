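"""Cross-species sRNA conservation: homology links, Venn partitioning,
chromosomal-compartment summaries, the conserved small-peptide screen and
convergent-pair synteny checks.

Conservation is any-hit by default: an sRNA is conserved in species S as
soon as one sufficiently good hit lands there (reciprocal-best mode is
available by flag).  Links come either from an external BLAST-style
tabular hit file (E-value < 1e-06, strict) or from the package's internal
local aligner, which reports no E-value — there the link criterion is
percent identity >= 70 over an alignment of >= 30 nt.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .align import naive_local_align, peptide_similarity
from .model import GenomeModel, ValidationError

E_VALUE_CUTOFF = 1e-6
INTERNAL_MIN_PIDENT = 70.0
INTERNAL_MIN_ALN_LEN = 30
#: Raw Smith-Waterman score floor for internal links.  The internal
#: aligner is uncalibrated (no E-value), and in >70% GC sequence chance
#: local alignments routinely reach 70% identity over 30+ nt — but they
#: score far below genuine sRNA homologies, which align near full length.
#: The score floor plays the role the E-value cutoff plays for an
#: external search engine.
INTERNAL_MIN_SCORE = 50

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODONS = ("ATG", "GTG")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_species: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError("negative E-value")
        if not (0 <= self.percent_identity <= 100):
            raise ValidationError("percent identity outside [0, 100]")


@dataclass
class ConservationSummary:
    """Per-compartment counts of unique vs conserved sRNAs (table shape:
    compartment, n sRNAs, n unique, n conserved, % conserved)."""

    rows: list[tuple[str, int, int, int, float]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["compartment", "n_srnas", "n_unique", "n_conserved",
                     "pct_conserved"],
        )

    @property
    def total(self) -> int:
        return sum(r[1] for r in self.rows)


def srna_catalog_size(n_previously_confirmed: int, n_novel: int) -> int:
    """Total sRNA catalog after a survey: previously confirmed sRNAs plus
    newly identified ones (novel calls are those not matching any prior
    entry, so the union is a plain sum)."""
    if min(n_previously_confirmed, n_novel) < 0:
        raise ValidationError("counts must be non-negative")
    return n_previously_confirmed + n_novel


def pct_conserved(n_conserved: int, n_total: int) -> float:
    """Percentage conserved at one decimal (half-up); exactly 0.0 when none."""
    if n_total <= 0:
        raise ValidationError("total must be positive")
    if n_conserved == 0:
        return 0.0
    from .coverage import display_round

    return display_round(100.0 * n_conserved / n_total)


# ---------------------------------------------------------------------------
# Homology links

def links_from_hits(
    hits: list[HomologyHit],
    known_queries: set[str],
    e_cutoff: float = E_VALUE_CUTOFF,
) -> set[tuple[str, str]]:
    """(query sRNA id, subject species) pairs supported by a hit with
    E-value strictly below the cutoff."""
    links = set()
    for h in hits:
        if h.query_id not in known_queries:
            raise ValidationError(f"hit references unknown sRNA {h.query_id!r}")
        if h.e_value < e_cutoff:
            links.add((h.query_id, h.subject_species))
    return links


def links_from_alignment(
    seqs_by_species: dict[str, dict[str, str]],
    min_pident: float = INTERNAL_MIN_PIDENT,
    min_aln_len: int = INTERNAL_MIN_ALN_LEN,
    min_score: int = INTERNAL_MIN_SCORE,
    reciprocal: bool = False,
) -> tuple[set[tuple[str, str]], list[HomologyHit]]:
    """All-against-all cross-species linking with the internal aligner.

    Sequences are transcript-oriented, so homologs align directly without
    reverse-complement search.  Returns the link set plus hit records (with
    E-value 0.0 as a placeholder: the internal aligner is uncalibrated).
    """
    links: set[tuple[str, str]] = set()
    hits: list[HomologyHit] = []
    species_of = {
        sid: sp for sp, seqs in seqs_by_species.items() for sid in seqs
    }
    # best-scoring qualifying partner per (id, other species), for the
    # optional reciprocal-best mode
    best: dict[tuple[str, str], tuple[float, str]] = {}
    for sp_a, sp_b in itertools.combinations(sorted(seqs_by_species), 2):
        for qid, qseq in seqs_by_species[sp_a].items():
            for sid, sseq in seqs_by_species[sp_b].items():
                aln = naive_local_align(qseq, sseq)
                if (
                    aln.percent_identity >= min_pident
                    and aln.alignment_length >= min_aln_len
                    and aln.score >= min_score
                ):
                    score = aln.percent_identity * aln.alignment_length
                    hits.append(
                        HomologyHit(qid, sp_b, sid, aln.percent_identity,
                                    aln.alignment_length, 0.0)
                    )
                    hits.append(
                        HomologyHit(sid, sp_a, qid, aln.percent_identity,
                                    aln.alignment_length, 0.0)
                    )
                    links.add((qid, sp_b))
                    links.add((sid, sp_a))
                    for a, b, sp in ((qid, sid, sp_b), (sid, qid, sp_a)):
                        key = (a, sp)
                        if key not in best or (score, b) > best[key]:
                            best[key] = (score, b)
    if reciprocal:
        out = set()
        for (qid, sp), (_, sid) in best.items():
            back = best.get((sid, species_of[qid]))
            if back is not None and back[1] == qid:
                out.add((qid, sp))
        links = out
    return links, hits


def build_homology_sets(
    srna_ids_by_species: dict[str, list[str]],
    links: set[tuple[str, str]],
) -> dict[str, frozenset[str]]:
    """Map every sRNA id to the frozenset of *other* species it is
    conserved in (empty set = species-unique)."""
    out = {}
    for sp, ids in srna_ids_by_species.items():
        others = set(srna_ids_by_species) - {sp}
        for sid in ids:
            out[sid] = frozenset(o for o in others if (sid, o) in links)
    return out


def venn_counts(
    srna_ids_by_species: dict[str, list[str]],
    conserved_in: dict[str, frozenset[str]],
) -> dict[tuple[str, frozenset[str]], int]:
    """Per-species counts of each conservation pattern.

    Keys are (species, frozenset of other species shared with); the
    species' total sRNA count is the sum over its patterns.
    """
    counts: dict[tuple[str, frozenset[str]], int] = {}
    for sp, ids in srna_ids_by_species.items():
        for sid in ids:
            key = (sp, conserved_in[sid])
            counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Compartment summary

def compartment_summary(
    srnas: list,
    model: GenomeModel,
    conserved_in: dict[str, frozenset[str]],
) -> ConservationSummary:
    """Per-compartment conservation table for one species.

    Each sRNA maps to exactly one compartment by its start position;
    "conserved" means conserved in at least one other species.  An sRNA
    outside every compartment is a partition violation and raises.
    """
    if model.compartments is None:
        raise ValidationError("model has no compartments")
    order: list[str] = []
    for rid in model.compartments:
        for label, _, _ in model.compartments[rid]:
            if label not in order:
                order.append(label)
    tally = {label: [0, 0] for label in order}  # label -> [total, conserved]
    for call in srnas:
        label = model.compartment_of(call.replicon_id, call.start)
        key = call.name if call.name is not None else f"{call.replicon_id}:{call.start}"
        tally[label][0] += 1
        if conserved_in.get(key):
            tally[label][1] += 1
    rows = []
    for label in order:
        n, c = tally[label]
        rows.append(
            (label, n, n - c, c, pct_conserved(c, n) if n else 0.0)
        )
    return ConservationSummary(rows)


def summary_from_counts(
    rows: list[tuple[str, int, int]]
) -> ConservationSummary:
    """Build the conservation table from (compartment, n, n_conserved)
    counts directly — the summary arithmetic without the calling stages."""
    out = []
    for label, n, c in rows:
        if c > n:
            raise ValidationError(f"{label}: conserved exceeds total")
        out.append((label, n, n - c, c, pct_conserved(c, n) if n else 0.0))
    return ConservationSummary(out)


# ---------------------------------------------------------------------------
# Conserved small-peptide screen

@dataclass(frozen=True)
class PeptideScreenParams:
    max_len_diff: float = 0.10    # relative ORF length difference
    min_similarity: float = 0.65  # grouped-similarity over alignment length
    min_orf_codons: int = 20      # excludes start codon? no: total codons incl. start

    def __post_init__(self) -> None:
        if not (0 < self.max_len_diff <= 1 and 0 < self.min_similarity <= 1):
            raise ValidationError("thresholds must lie in (0, 1]")


def find_orfs(seq: str, min_codons: int = 20) -> list[tuple[int, int, str]]:
    """Same-strand ORFs in all three frames: start ATG/GTG, stop
    TAA/TAG/TGA.  Returns (start, end, peptide) with end past the stop;
    the peptide excludes the stop."""
    from Bio.Seq import Seq

    seq = seq.upper()
    orfs = []
    for frame in range(3):
        i = frame
        while i + 3 <= len(seq):
            if seq[i : i + 3] in START_CODONS:
                j = i + 3
                while j + 3 <= len(seq):
                    if seq[j : j + 3] in STOP_CODONS:
                        n_codons = (j - i) // 3
                        if n_codons >= min_codons:
                            pep = str(Seq(seq[i:j]).translate())
                            # bacterial initiator is Met regardless of codon
                            pep = "M" + pep[1:]
                            orfs.append((i, j + 3, pep))
                        i = j  # next search continues after this ORF
                        break
                    j += 3
                else:
                    break
            i += 3
    return sorted(orfs)


def screen_small_peptides(
    groups: list[list[str]],
    sequences: dict[str, str],
    params: PeptideScreenParams = PeptideScreenParams(),
) -> list[list[str]]:
    """Which conserved sRNA homolog groups could encode a conserved peptide.

    A group (sRNA ids conserved in >= 2 species) is a candidate iff every
    member carries a same-strand ORF and some choice of one ORF per member
    gives pairwise relative length differences <= max_len_diff and pairwise
    grouped similarity >= min_similarity.
    """
    candidates = []
    for group in groups:
        if len(group) < 2:
            continue
        orf_sets = []
        for sid in group:
            if sid not in sequences:
                raise ValidationError(f"missing sequence for group member {sid!r}")
            orfs = find_orfs(sequences[sid], params.min_orf_codons)
            if not orfs:
                orf_sets = None
                break
            orf_sets.append([pep for (_, _, pep) in orfs])
        if not orf_sets:
            continue
        if _compatible_orfs(orf_sets, params):
            candidates.append(group)
    return candidates


def _compatible_orfs(orf_sets: list[list[str]], params: PeptideScreenParams) -> bool:
    for combo in itertools.product(*orf_sets):
        ok = True
        for pa, pb in itertools.combinations(combo, 2):
            la, lb = len(pa), len(pb)
            if abs(la - lb) / max(la, lb) > params.max_len_diff:
                ok = False
                break
            if peptide_similarity(pa, pb) < params.min_similarity:
                ok = False
                break
        if ok:
            return True
    return False


# ---------------------------------------------------------------------------
# Convergent-pair synteny

def pair_orientation_conserved(
    pair: tuple[str, str],
    other_model: GenomeModel,
    homolog_map: dict[str, str],
    adjacency_allowance: int = 1,
) -> str:
    """Is a convergent gene pair still convergent in another species?

    Returns 'convergent', 'not_convergent' or 'absent' (a homolog is
    missing).  Convergent: both homologs on the same replicon, separated by
    at most ``adjacency_allowance`` intervening genes, strands pointing
    toward each other.
    """
    ha, hb = homolog_map.get(pair[0]), homolog_map.get(pair[1])
    if ha is None or hb is None or ha not in other_model or hb not in other_model:
        return "absent"
    ga, gb = other_model.gene(ha), other_model.gene(hb)
    if ga.replicon_id != gb.replicon_id:
        return "not_convergent"
    left, right = (ga, gb) if ga.start <= gb.start else (gb, ga)
    genes = other_model.genes_on(ga.replicon_id)
    between = [
        g for g in genes
        if g.start >= left.end and g.end <= right.start
        and g.gene_id not in (ga.gene_id, gb.gene_id)
    ]
    if len(between) > adjacency_allowance:
        return "not_convergent"
    if left.strand == "+" and right.strand == "-":
        return "convergent"
    return "not_convergent"
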