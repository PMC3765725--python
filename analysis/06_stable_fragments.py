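"""Detect stable RNA fragments (>100x over the gene-body baseline in the
short library), classify their location, and profile the nucleotide /
codon content of the regions and their 15-nt upstream windows."""
from collections import Counter

from strepnc.fragments import (
    codon_usage_table,
    content_analysis,
    detect_stable_regions,
    rank_stable_regions,
    regions_to_dataframe,
)

from _common import load_all, outdir

if __name__ == "__main__":
    out = outdir("06_stable_fragments")
    for sp, d in load_all().items():
        regions = detect_stable_regions(d.model, d.tracks)
        usage = codon_usage_table(d.model)
        stats = [content_analysis(r, d.model, usage) for r in regions]
        regions_to_dataframe(regions, stats).to_csv(
            out / f"stable_regions_{sp}.tsv", sep="\t", index=False
        )
        top = rank_stable_regions(regions, k=20)
        classes = Counter(r.location_class for r in regions)
        at_up = sum(s.at_upstream_window for s in stats) / len(stats)
        at_cds = sum(s.at_cds for s in stats) / len(stats)
        print(
            f"{sp}: {len(regions)} stable regions {dict(sorted(classes.items()))}; "
            f"top fold {top[0].fold_enrichment:.0f}x; "
            f"mean AT upstream {at_up:.3f} vs CDS {at_cds:.3f}"
        )
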