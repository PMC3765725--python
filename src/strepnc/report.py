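"""Cross-module reporting: secondary-metabolite cluster annotation."""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .antisense import AntisenseCall
from .intervals import overlap_length

ANTISENSE_CATEGORIES = ("asRNA", "cutoRNA", "divergent_overlap")


@dataclass
class ClusterAnnotation:
    cluster_id: str
    replicon_id: str
    start: int
    end: int
    calls_overlapping: dict[str, int] = field(default_factory=dict)

    @property
    def has_antisense(self) -> bool:
        return sum(self.calls_overlapping.get(c, 0) for c in ANTISENSE_CATEGORIES) > 0


def annotate_clusters(
    calls: list[AntisenseCall],
    clusters: list[tuple[str, str, int, int]],
) -> tuple[list[ClusterAnnotation], float]:
    """Count calls per cluster and the fraction of clusters with antisense.

    ``clusters`` rows are (cluster_id, replicon_id, start, end).  A call
    counts toward a cluster iff their intervals overlap by >= 1 nt; a call
    spanning two clusters counts in both.
    """
    annotations = []
    n_with = 0
    for cid, rid, start, end in clusters:
        counts: dict[str, int] = {}
        for c in calls:
            if c.replicon_id != rid:
                continue
            if overlap_length((start, end), (c.start, c.end)) >= 1:
                counts[c.category] = counts.get(c.category, 0) + 1
        ann = ClusterAnnotation(cid, rid, start, end, counts)
        annotations.append(ann)
        n_with += ann.has_antisense
    fraction = n_with / len(clusters) if clusters else 0.0
    return annotations, fraction


def clusters_to_dataframe(annotations: list[ClusterAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        row = {
            "cluster_id": a.cluster_id,
            "replicon_id": a.replicon_id,
            "start": a.start,
            "end": a.end,
            "has_antisense": a.has_antisense,
        }
        for cat in ANTISENSE_CATEGORIES + ("unclassified",):
            row[f"n_{cat}"] = a.calls_overlapping.get(cat, 0)
        rows.append(row)
    return pd.DataFrame(rows)
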