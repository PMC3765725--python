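"""Run configuration and manifests.

A single YAML file (or keyword overrides) drives the whole pipeline;
every parameter that can affect a call is echoed verbatim into the run
manifest so results are reproducible from the manifest alone.  Unknown
keys are rejected rather than ignored.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .antisense import ReadthroughParams
from .conserve import INTERNAL_MIN_ALN_LEN, INTERNAL_MIN_PIDENT, INTERNAL_MIN_SCORE
from .fragments import FragmentParams
from .model import ValidationError
from .srna import SrnaParams


@dataclass(frozen=True)
class SpeciesConfig:
    label: str
    prefix: str              # sRNA name prefix, e.g. "scr"
    fixture_dir: str | None = None
    t_mev: float = 10.0
    t_peak: float = 20.0


@dataclass(frozen=True)
class ConservationParams:
    min_pident: float = INTERNAL_MIN_PIDENT
    min_aln_len: int = INTERNAL_MIN_ALN_LEN
    min_score: int = INTERNAL_MIN_SCORE
    reciprocal: bool = False
    e_cutoff: float = 1e-6


@dataclass(frozen=True)
class RunConfig:
    species: tuple[SpeciesConfig, ...] = (
        SpeciesConfig("S1", "s1r"),
        SpeciesConfig("S2", "s2r"),
        SpeciesConfig("S3", "s3r"),
    )
    seed: int = 0
    out_dir: str = "results/run"
    readthrough: ReadthroughParams = field(default_factory=ReadthroughParams)
    srna: SrnaParams = field(default_factory=SrnaParams)
    fragments: FragmentParams = field(default_factory=FragmentParams)
    conservation: ConservationParams = field(default_factory=ConservationParams)
    skip: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTION_TYPES = {
    "readthrough": ReadthroughParams,
    "srna": SrnaParams,
    "fragments": FragmentParams,
    "conservation": ConservationParams,
}


def _build(cls, data: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    kwargs: dict = {}
    if "species" in data:
        kwargs["species"] = tuple(
            _build(SpeciesConfig, sp, f"species[{i}]")
            for i, sp in enumerate(data.pop("species"))
        )
    for key, cls in _SECTION_TYPES.items():
        if key in data:
            kwargs[key] = _build(cls, data.pop(key), key)
    if "skip" in data:
        kwargs["skip"] = tuple(data.pop("skip"))
    for key in ("seed", "out_dir"):
        if key in data:
            kwargs[key] = data.pop(key)
    if data:
        raise ValidationError(f"unknown configuration keys: {sorted(data)}")
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: top level must be a mapping")
    return config_from_dict(data)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    config: RunConfig, out_path: str | Path, inputs: list[str | Path] = ()
) -> None:
    from . import __version__

    manifest = {
        "strepnc_version": __version__,
        "parameters": config.to_dict(),
        "inputs": {
            str(p): file_checksum(p) for p in inputs if Path(p).is_file()
        },
    }
    with open(out_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
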