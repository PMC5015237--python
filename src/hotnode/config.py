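"""Run configuration: one YAML-loadable object bundling every stage's knobs.

Unknown keys are rejected — a typo in a threshold name must fail loudly, not
silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classify import ClassifierConfig
from .imaging import BackgroundThreshold, ResampleSpec
from .stats import MatchSpec
from .tissue import HUThresholds

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    resample: ResampleSpec = field(default_factory=ResampleSpec)
    background: BackgroundThreshold = field(default_factory=BackgroundThreshold)
    hu_thresholds: HUThresholds = field(default_factory=HUThresholds)
    closing_radius_mm: float = 3.0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    match: MatchSpec = field(default_factory=MatchSpec)
    suppress_before_resample: bool = False
    log_level: str = "INFO"

    def sha256(self) -> str:
        """Hash of the canonical JSON form; part of the output provenance."""
        return hashlib.sha256(
            json.dumps(_as_jsonable(self), sort_keys=True).encode()).hexdigest()


_SECTIONS = {
    "resample": ResampleSpec,
    "background": BackgroundThreshold,
    "hu_thresholds": HUThresholds,
    "classifier": ClassifierConfig,
    "match": MatchSpec,
}


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        coerced[k] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file and/or an override mapping."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    if overrides:
        for k, v in overrides.items():
            if isinstance(v, dict) and isinstance(data.get(k), dict):
                data[k].update(v)
            else:
                data[k] = v
    top_names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_names
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            kwargs[key] = _build(_SECTIONS[key], value, key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(x) for x in obj]
    return obj
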