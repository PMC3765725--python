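"""Annotate secondary-metabolite-style gene clusters with overlapping
antisense calls and report the fraction of clusters carrying antisense
transcription of at least one class."""
import dataclasses

from strepnc.antisense import ReadthroughParams, classify_antisense
from strepnc.coverage import ThresholdSet, compute_gene_stats, flag_antisense_candidates
from strepnc.report import annotate_clusters, clusters_to_dataframe

from _common import load_all, outdir

if __name__ == "__main__":
    out = outdir("07_clusters")
    for sp, d in load_all().items():
        thresholds = ThresholdSet(sp, 10.0, 20.0)
        stats = compute_gene_stats(d.model, d.tracks, "long")
        flagged = flag_antisense_candidates(stats, thresholds)
        params = dataclasses.replace(ReadthroughParams(), t_rt=thresholds.t_mev)
        primary, _, _ = classify_antisense(d.model, d.tracks, flagged, params)
        rid = next(iter(d.model.replicons))
        rows = [(cid, rid, s, e) for cid, s, e in d.clusters]
        annotations, fraction = annotate_clusters(primary, rows)
        clusters_to_dataframe(annotations).to_csv(
            out / f"cluster_annotation_{sp}.tsv", sep="\t", index=False
        )
        print(f"{sp}: {100 * fraction:.0f}% of {len(rows)} clusters carry "
              f"antisense calls of at least one class")
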