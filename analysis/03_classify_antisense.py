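"""Classify flagged antisense signal into asRNA / cutoRNA /
divergent-overlap / unclassified calls from genomic context and coverage
continuity, and check recovery against the planted truth."""
import dataclasses
from collections import Counter

import pandas as pd

from strepnc.antisense import ReadthroughParams, calls_to_dataframe, calls_to_gff3, classify_antisense
from strepnc.coverage import ThresholdSet, compute_gene_stats, flag_antisense_candidates
from strepnc.evaluate import score_antisense
from strepnc.simulate import PlantedFeature

from _common import FIXTURE, load_all, outdir

if __name__ == "__main__":
    out = outdir("03_antisense")
    data = load_all()
    truth = pd.read_csv(FIXTURE / "planted_features.tsv", sep="\t")
    for sp, d in data.items():
        thresholds = ThresholdSet(sp, 10.0, 20.0)
        stats = compute_gene_stats(d.model, d.tracks, "long")
        flagged = flag_antisense_candidates(stats, thresholds)
        params = dataclasses.replace(ReadthroughParams(), t_rt=thresholds.t_mev)
        primary, pairs, _ = classify_antisense(d.model, d.tracks, flagged, params)
        calls_to_dataframe(primary).to_csv(
            out / f"antisense_calls_{sp}.tsv", sep="\t", index=False
        )
        calls_to_gff3(primary, out / f"antisense_calls_{sp}.gff3")
        counts = Counter(c.category for c in primary)
        planted = [
            PlantedFeature(**{
                "feature_id": r.feature_id, "species": r.species, "kind": r.kind,
                "replicon_id": r.replicon_id, "start": r.start, "end": r.end,
                "strand": r.strand, "expression_level": r.expression_level,
                "partner_gene_id": r.partner_gene_id if isinstance(r.partner_gene_id, str) else None,
                "gene_id": r.gene_id if isinstance(r.gene_id, str) else None,
            })
            for r in truth[truth.species == sp].itertuples()
            if r.kind in ("asRNA", "cutoRNA", "divergent_overlap")
        ]
        recovery = score_antisense(planted, primary)
        print(f"{sp}: calls by category {dict(sorted(counts.items()))}")
        for kind, rep in recovery.items():
            print(f"   planted {kind}: {rep.n_recovered}/{rep.n_planted} recovered")
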