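"""Run configuration: YAML/JSON scenario files -> typed config objects.

A run config collects every tunable of a simulated test run.  Unknown keys
are rejected (typos should fail loudly), and the fully-resolved config —
defaults included — is serialized into every output for provenance, together
with its SHA-256 hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import EngineConfig
from .errors import ConfigError
from .field_map import VariogramConfig
from .geometry import ScreenModel
from .observer import ObserverParams, Scotoma, TrueField


def _build(cls, data: dict | None, section: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    data = dict(data or {})
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc


def _build_field(data: dict | None) -> TrueField:
    data = dict(data or {})
    scotomas = data.pop("scotomas", [])
    if not isinstance(scotomas, list):
        raise ConfigError("field.scotomas must be a list")
    built = tuple(_build(Scotoma, {**s, "center": tuple(s.get("center", (0.0, -1.0)))},
                         f"field.scotomas[{i}]")
                  for i, s in enumerate(scotomas))
    base = _build(TrueField, data, "field")
    return dataclasses.replace(base, scotomas=built)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to run a simulated test end to end."""

    screen: ScreenModel = field(default_factory=ScreenModel)
    engine: EngineConfig = field(default_factory=EngineConfig)
    variogram: VariogramConfig = field(default_factory=VariogramConfig)
    observer: ObserverParams = field(default_factory=ObserverParams)
    true_field: TrueField = field(default_factory=TrueField)
    stimulus_luminance_cdm2: float = 300.0
    background_luminance_cdm2: float = 31.0
    laterality: str = "right"
    hfa_measurement_sd_db: float = 1.0
    resolution_deg: float = 0.5
    db_cutoff: float = 25.0
    hr_cutoff: float = 0.5
    seed: int = 0

    _TOP_LEVEL = ("screen", "engine", "variogram", "observer", "field",
                  "stimulus_luminance_cdm2", "background_luminance_cdm2",
                  "laterality", "hfa_measurement_sd_db", "resolution_deg",
                  "db_cutoff", "hr_cutoff", "seed")

    @classmethod
    def from_dict(cls, data: dict | None) -> "RunConfig":
        data = dict(data or {})
        unknown = set(data) - set(cls._TOP_LEVEL)
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs = dict(
            screen=_build(ScreenModel, data.get("screen"), "screen"),
            engine=_build(EngineConfig, data.get("engine"), "engine"),
            variogram=_build(VariogramConfig, data.get("variogram"), "variogram"),
            observer=_build(ObserverParams, data.get("observer"), "observer"),
            true_field=_build_field(data.get("field")),
        )
        for key in cls._TOP_LEVEL[5:]:
            if key in data:
                kwargs[key] = data[key]
        cfg = cls(**kwargs)
        if cfg.laterality not in ("left", "right"):
            raise ConfigError(f"laterality must be left/right, got {cfg.laterality!r}")
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["field"] = d.pop("true_field")
        d["field"]["scotomas"] = [dataclasses.asdict(s)
                                  for s in self.true_field.scotomas]
        return d

    def config_hash(self) -> str:
        """SHA-256 over the canonical JSON of the fully-resolved config."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    def with_seed(self, seed: int | None) -> "RunConfig":
        return self if seed is None else dataclasses.replace(self, seed=int(seed))
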