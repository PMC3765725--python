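"""Shared plumbing for the numbered analysis drivers."""
from pathlib import Path

from strepnc.config import SpeciesConfig
from strepnc.pipeline import SpeciesData, load_species_data

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
FIXTURE = RESULTS / "fixture"

SPECIES = ("S1", "S2", "S3")
PREFIXES = {"S1": "s1r", "S2": "s2r", "S3": "s3r"}


def species_configs() -> list[SpeciesConfig]:
    return [
        SpeciesConfig(sp, PREFIXES[sp], fixture_dir=str(FIXTURE / sp))
        for sp in SPECIES
    ]


def load_all() -> dict[str, SpeciesData]:
    if not FIXTURE.is_dir():
        raise SystemExit(
            "fixture not found - run `python analysis/01_simulate_fixture.py` first"
        )
    return {cfg.label: load_species_data(cfg) for cfg in species_configs()}


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
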