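"""Small shared helpers for run/island arithmetic on depth arrays."""
from __future__ import annotations

import numpy as np


def runs_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True in a boolean array."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def merge_close(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    """Merge runs separated by at most ``gap`` positions."""
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe <= gap:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def islands(depth: np.ndarray, floor: float, gap: int) -> list[tuple[int, int]]:
    """Maximal runs with depth >= floor, sub-floor gaps <= gap bridged."""
    return merge_close(runs_true(depth >= floor), gap)


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
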