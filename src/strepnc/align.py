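"""Local nucleotide alignment and peptide similarity scoring.

`naive_local_align` is a plain Smith-Waterman with linear gap penalty,
used to link candidate sRNA homologs on genomes where no external homology
search has been run.  It reports no E-value; callers link sequences on
percent identity over a minimum alignment length instead.  The DP fill is
numba-compiled; traceback is pure Python.

Peptide similarity for the small-ORF screen uses Biopython's global
aligner plus a fixed amino-acid similarity partition.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

DEFAULT_MATCH = 2
DEFAULT_MISMATCH = -3
DEFAULT_GAP = -5

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}

#: Amino-acid similarity partition used by the conserved-peptide screen.
SIMILARITY_GROUPS = (
    frozenset("ILVM"),
    frozenset("FYW"),
    frozenset("KRH"),
    frozenset("DE"),
    frozenset("NQ"),
    frozenset("ST"),
    frozenset("AG"),
    frozenset("C"),
    frozenset("P"),
)

_GROUP_OF = {aa: i for i, grp in enumerate(SIMILARITY_GROUPS) for aa in grp}


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    percent_identity: float
    alignment_length: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def empty(self) -> bool:
        return self.alignment_length == 0


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"non-DNA character {e.args[0]!r} in sequence") from None


@njit(cache=False)
def _sw_fill(a, b, match, mismatch, gap):  # pragma: no cover - numba kernel
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1] and a[i - 1] != 4:
                s = match
            else:
                s = mismatch
            best = H[i - 1, j - 1] + s
            up = H[i - 1, j] + gap
            if up > best:
                best = up
            left = H[i, j - 1] + gap
            if left > best:
                best = left
            if best < 0:
                best = 0
            H[i, j] = best
    return H


def naive_local_align(
    seq_a: str,
    seq_b: str,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment with linear gap penalty.

    Ties between equally scoring alignments are broken deterministically:
    leftmost start in ``seq_a``, then leftmost start in ``seq_b``.  Empty
    input (or no positive-scoring alignment) yields score 0 and an empty
    alignment.  Percent identity is matched columns over alignment length,
    gap columns included in the denominator.
    """
    if not seq_a or not seq_b:
        return LocalAlignment(0, 0.0, 0, 0, 0, 0, 0)
    a, b = _encode(seq_a), _encode(seq_b)
    H = _sw_fill(a, b, np.int64(match), np.int64(mismatch), np.int64(gap))
    best = int(H.max())
    if best == 0:
        return LocalAlignment(0, 0.0, 0, 0, 0, 0, 0)
    # All maximal cells, traced back; keep the alignment with the leftmost
    # start in a, then in b.  Tie sets are tiny in practice.
    ends = np.argwhere(H == best)
    candidates = []
    for ei, ej in ends:
        aln = _traceback(H, a, b, int(ei), int(ej), match, mismatch, gap)
        candidates.append(aln)
    candidates.sort(key=lambda x: (x.a_start, x.b_start, x.a_end, x.b_end))
    chosen = candidates[0]
    return LocalAlignment(best, chosen.percent_identity, chosen.alignment_length,
                          chosen.a_start, chosen.a_end, chosen.b_start, chosen.b_end)


def _traceback(H, a, b, i, j, match, mismatch, gap) -> LocalAlignment:
    matches = 0
    length = 0
    end_i, end_j = i, j
    while i > 0 and j > 0 and H[i, j] > 0:
        is_match = a[i - 1] == b[j - 1] and a[i - 1] != 4
        s = match if is_match else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            matches += int(is_match)
            length += 1
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            length += 1
            i -= 1
        elif H[i, j] == H[i, j - 1] + gap:
            length += 1
            j -= 1
        else:  # unreachable for a well-formed matrix
            raise AssertionError("inconsistent traceback")
    pid = 100.0 * matches / length if length else 0.0
    return LocalAlignment(int(H[end_i, end_j]), pid, length, i, end_i, j, end_j)


# ---------------------------------------------------------------------------
# Peptide similarity (conserved small-ORF screen)

def peptide_similarity(pep_a: str, pep_b: str) -> float:
    """Fraction of alignment columns that are identical or within one
    similarity group, under a global alignment; gap columns count as
    dissimilar.  Returns a value in [0, 1]."""
    from Bio import Align

    if not pep_a or not pep_b:
        return 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    alignment = aligner.align(pep_a, pep_b)[0]
    col_a, col_b = alignment[0], alignment[1]
    similar = 0
    for x, y in zip(col_a, col_b):
        if x == "-" or y == "-":
            continue
        if x == y or _GROUP_OF.get(x) == _GROUP_OF.get(y) and x in _GROUP_OF:
            similar += 1
    return similar / len(col_a) if len(col_a) else 0.0
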