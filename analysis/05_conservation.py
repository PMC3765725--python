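"""Cross-species sRNA conservation: internal pairwise alignment links,
Venn partitioning, per-compartment conservation tables, and the conserved
small-peptide screen."""
import pandas as pd

from strepnc.conserve import (
    build_homology_sets,
    compartment_summary,
    links_from_alignment,
    screen_small_peptides,
    venn_counts,
)
from strepnc.pipeline import _call_sequence
from strepnc.srna import SrnaParams, call_srnas

from _common import PREFIXES, load_all, outdir

if __name__ == "__main__":
    out = outdir("05_conservation")
    data = load_all()
    calls, seqs, ids = {}, {}, {}
    for sp, d in data.items():
        calls[sp], _ = call_srnas(d.model, d.tracks, SrnaParams(), PREFIXES[sp])
        seqs[sp] = {c.name: _call_sequence(d.model, c) for c in calls[sp]}
        ids[sp] = [c.name for c in calls[sp]]

    links, hits = links_from_alignment(seqs)
    conserved_in = build_homology_sets(ids, links)
    venn = venn_counts(ids, conserved_in)
    rows = [
        {"species": sp, "shared_with": ",".join(sorted(p)) or "-", "n": n}
        for (sp, p), n in sorted(venn.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1])))
    ]
    pd.DataFrame(rows).to_csv(out / "venn_counts.tsv", sep="\t", index=False)
    for sp in data:
        pat = {r["shared_with"]: r["n"] for r in rows if r["species"] == sp}
        print(f"{sp}: conservation patterns {pat}")
        summary = compartment_summary(calls[sp], data[sp].model, conserved_in)
        summary.to_dataframe().to_csv(
            out / f"compartment_summary_{sp}.tsv", sep="\t", index=False
        )
    # small-peptide screen over groups conserved in >= 2 species
    groups = []
    for sp in data:
        for c in calls[sp]:
            partners = conserved_in.get(c.name, frozenset())
            if partners:
                group = [c.name] + [
                    h.subject_id for h in hits
                    if h.query_id == c.name and h.subject_species in partners
                ]
                groups.append(sorted(set(group)))
    groups = [list(g) for g in {tuple(g) for g in groups}]
    all_seqs = {name: s for d_ in seqs.values() for name, s in d_.items()}
    candidates = screen_small_peptides(groups, all_seqs)
    print(f"peptide screen: {len(candidates)}/{len(groups)} conserved groups "
          f"could encode a conserved small protein")
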