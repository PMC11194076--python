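"""Run configuration: YAML-backed settings and deterministic seed derivation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .align import SizeBins
from .chemistry import ChemistryParams
from .fragments import PopulationMix, SizeDist
from .genome import ConfigError, GenomeConfig
from .methylome import MethylomeParams
from .protocol import normalize_protocol

__all__ = ["RunConfig", "stage_seed", "load_config", "ConfigError"]

DEFAULT_ANALYSES = {
    "size_profile": True,
    "per_bin_methylation": True,
    "gquad": True,
    "cpg_density": True,
    "conversion_qc": True,
    "element_composition": True,
    "observed_ratio": True,
    "tss_profile": True,
    "feature_trend": True,
    "dmr": False,
    "deconvolution": False,
}


def stage_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed: re-running one stage never perturbs another."""
    return (zlib.crc32(stage.encode()) ^ int(root_seed)) % (2**31)


@dataclass
class RunConfig:
    seed: int = 1
    protocol: str = "5mCAdpBS"
    n_fragments: int = 20_000
    read_len: int = 150
    sequencing_error_rate: float = 0.001
    outdir: str = "uscfmeth_out"
    panel_path: str | None = None
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    methylome: MethylomeParams = field(default_factory=MethylomeParams)
    chemistry: ChemistryParams = field(default_factory=ChemistryParams)
    mix: PopulationMix = field(default_factory=PopulationMix)
    bins: SizeBins = field(default_factory=SizeBins)
    analyses: dict[str, bool] = field(default_factory=lambda: dict(DEFAULT_ANALYSES))

    def __post_init__(self) -> None:
        self.protocol = normalize_protocol(self.protocol)
        if self.n_fragments < 1:
            raise ConfigError("n_fragments must be positive")
        for key in self.analyses:
            if key not in DEFAULT_ANALYSES:
                raise ConfigError(f"unknown analysis toggle: {key!r}")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_NESTED = {
    "genome": GenomeConfig,
    "methylome": MethylomeParams,
    "chemistry": ChemistryParams,
    "bins": SizeBins,
}


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in names:
            raise ConfigError(f"unknown key {key!r} for {cls.__name__}")
    return cls(**data)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML run configuration, applying keyword overrides on top."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})

    kwargs: dict = {}
    for key, value in data.items():
        if key in _NESTED:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _build(_NESTED[key], value)
        elif key == "mix":
            if not isinstance(value, dict):
                raise ConfigError("section 'mix' must be a mapping")
            sizes = value.pop("sizes", None)
            if sizes is not None:
                from .fragments import DEFAULT_SIZES

                parsed = {
                    pop: _build(SizeDist, sd) if isinstance(sd, dict) else sd
                    for pop, sd in sizes.items()
                }
                value["sizes"] = {**DEFAULT_SIZES, **parsed}
            kwargs[key] = _build(PopulationMix, value)
        elif key == "analyses":
            merged = dict(DEFAULT_ANALYSES)
            merged.update(value)
            kwargs[key] = merged
        else:
            kwargs[key] = value
    return _build(RunConfig, kwargs)
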