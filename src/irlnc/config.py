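"""Pipeline configuration: nested dataclasses with YAML loading, strict
(unknown keys rejected) validation, and defaults mirroring the published
parameters (lncRES cutoff 0.995, FDR 0.05; consensus reps=1000, pItem=0.8,
pFeature=1, euclidean)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io import ConfigurationError
from .lncres import LncresParams
from .synth import SynthConfig


@dataclass
class PrecleanParams:
    min_iqr: float = 0.0
    quantile: bool = False


@dataclass
class DEParams:
    alpha: float = 0.05
    lfc: float = 1.0
    moderated: bool = True

    def validate(self) -> "DEParams":
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("de.alpha must lie in (0, 1]")
        if self.lfc < 0:
            raise ConfigurationError("de.lfc must be >= 0")
        return self


@dataclass
class NetworkParams:
    top_k_pathways: int = 5
    allow_list: list[str] | None = None
    pathway_gmt: str | None = None  # defaults to the immune collection


@dataclass
class SubtypeParams:
    k: int | str = "auto"            # fixed k or "auto" (delta-area)
    k_range: list[int] = field(default_factory=lambda: [2, 3, 4, 5])
    reps: int = 1000
    p_item: float = 0.8
    p_feature: float = 1.0
    distance: str = "euclidean"
    inner: str = "hierarchical"
    top_n: int = 50
    seed: int = 0

    def validate(self) -> "SubtypeParams":
        if min(self.k_range) < 2:
            raise ConfigurationError("subtype.k_range minimum must be >= 2")
        if not (0 < self.p_item <= 1 and 0 < self.p_feature <= 1):
            raise ConfigurationError("subtype.p_item/p_feature must lie in (0, 1]")
        if self.distance != "euclidean":
            raise ConfigurationError("only euclidean distance is supported")
        if self.k != "auto":
            if int(self.k) not in self.k_range:
                raise ConfigurationError("subtype.k must be 'auto' or a value in k_range")
        return self


@dataclass
class ProfileParams:
    tau: float = 1.0
    mode: str = "mxdiff"
    alpha: float = 0.05
    test: str = "wilcoxon"
    marker_gmt: str | None = None    # defaults to the packaged marker sets


@dataclass
class PipelineConfig:
    outdir: str = "irlnc_run"
    synth: SynthConfig = field(default_factory=SynthConfig)
    emit_pair: bool = True
    preclean: PrecleanParams = field(default_factory=PrecleanParams)
    de: DEParams = field(default_factory=DEParams)
    lncres: LncresParams = field(default_factory=LncresParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    subtype: SubtypeParams = field(default_factory=SubtypeParams)
    profile: ProfileParams = field(default_factory=ProfileParams)

    def validate(self) -> "PipelineConfig":
        self.synth.validate()
        self.de.validate()
        self.lncres.validate()
        self.subtype.validate()
        return self

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ConfigurationError(f"unknown config key(s) under '{path}': {unknown}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if isinstance(value, dict) and dataclasses.is_dataclass(_nested_type(fields[name])):
            kwargs[name] = _build(_nested_type(fields[name]), value, f"{path}.{name}")
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _nested_type(f: dataclasses.Field):
    mapping = {
        "synth": SynthConfig, "preclean": PrecleanParams, "de": DEParams,
        "lncres": LncresParams, "network": NetworkParams,
        "subtype": SubtypeParams, "profile": ProfileParams,
    }
    return mapping.get(f.name, object)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config (or defaults when *path* is None) and validate."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
        data = loaded
    config = _build(PipelineConfig, data, "root")
    if overrides:
        for key, value in overrides.items():
            section, _, leaf = key.partition(".")
            if leaf:
                setattr(getattr(config, section), leaf, value)
            else:
                setattr(config, section, value)
    return config.validate()
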