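import logging

import numpy as np
import pytest

from strepnc.config import RunConfig
from strepnc.model import GeneRecord, GenomeModel, Replicon, StrandedTrack, TrackSet
from strepnc.pipeline import SpeciesData, run_pipeline
from strepnc.simulate import SimConfig, simulate_species_set

logging.disable(logging.INFO)

FIXTURE_SEED = 1


def make_model(
    genes: list[tuple],
    length: int = 2000,
    rid: str = "chr",
    sequence: str | None = None,
    compartments=None,
) -> GenomeModel:
    """Tiny GenomeModel from (gene_id, start, end, strand[, feature_class])."""
    records = [
        GeneRecord(g[0], rid, g[1], g[2], g[3], g[4] if len(g) > 4 else "protein_coding")
        for g in genes
    ]
    return GenomeModel(
        replicons={rid: Replicon(rid, length, sequence)},
        genes=records,
        compartments={rid: compartments} if compartments else None,
    )


def make_tracks(
    model: GenomeModel, arrays: dict[tuple[str, str], np.ndarray] | None = None
) -> TrackSet:
    """TrackSet with all-zero tracks except the (strand, library) arrays given."""
    rid = next(iter(model.replicons))
    length = model.replicons[rid].length
    tracks = []
    for strand in ("+", "-"):
        for lib in ("long", "short"):
            depth = (arrays or {}).get((strand, lib))
            if depth is None:
                depth = np.zeros(length, dtype=np.int64)
            tracks.append(StrandedTrack(rid, strand, lib, depth))
    return TrackSet(tracks)


@pytest.fixture(scope="session")
def sim_result():
    """The default three-species fixture at a fixed seed."""
    return simulate_species_set(SimConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def pipeline_result(sim_result):
    """Full pipeline output on the default fixture (no files written)."""
    data = {
        sp: SpeciesData(sp, sim_result.models[sp], sim_result.tracks[sp],
                        sim_result.clusters[sp])
        for sp in sim_result.models
    }
    return run_pipeline(RunConfig(), data=data, write=False)
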