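"""Call intergenic sRNAs from expression islands, disambiguate them from
highly expressed UTR fragments, and name them after their right-flanking
protein-coding genes."""
from collections import Counter

from strepnc.srna import SrnaParams, call_srnas, srnas_to_dataframe, srnas_to_gff3

from _common import PREFIXES, load_all, outdir

if __name__ == "__main__":
    out = outdir("04_srnas")
    for sp, d in load_all().items():
        calls, companions = call_srnas(d.model, d.tracks, SrnaParams(), PREFIXES[sp])
        srnas_to_dataframe(calls).to_csv(out / f"srnas_{sp}.tsv", sep="\t", index=False)
        srnas_to_gff3(calls, out / f"srnas_{sp}.gff3")
        srnas_to_dataframe(companions).to_csv(
            out / f"srna_companions_{sp}.tsv", sep="\t", index=False
        )
        lengths = [c.length for c in calls]
        classes = Counter(c.classification for c in companions)
        print(
            f"{sp}: {len(calls)} sRNAs ({min(lengths)}-{max(lengths)} nt), "
            f"e.g. {', '.join(c.name for c in calls[:3])}; "
            f"companions {dict(sorted(classes.items()))}"
        )
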