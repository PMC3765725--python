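"""Generate the three-species synthetic transcriptome fixture.

Writes GFF3 annotation, GC-rich genome FASTA, four stranded bedGraph
coverage tracks per species (long/short library x plus/minus strand),
compartment and cluster BED files, and the planted-feature / homolog
truth tables that later stages are scored against.
"""
from collections import Counter

from strepnc.simulate import SimConfig, simulate_species_set, write_fixture

from _common import FIXTURE

SEED = 7

if __name__ == "__main__":
    result = simulate_species_set(SimConfig(seed=SEED))
    write_fixture(result, FIXTURE, force=True)
    kinds = Counter(f.kind for f in result.features)
    print(f"fixture written to {FIXTURE} (seed {SEED})")
    for sp, model in result.models.items():
        rep = next(iter(model.replicons.values()))
        print(f"  {sp}: {len(model.genes)} genes on {rep.length:,} nt")
    print("planted features:", dict(sorted(kinds.items())))
    print(f"homolog truth table: {len(result.homolog_pairs)} cross-species pairs")
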