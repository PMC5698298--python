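"""Run configuration: dataclass-backed, YAML round-trippable, strict keys."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from nanomap.calibration import Calibration
from nanomap.imageproc import SegmentConfig
from nanomap.labelcall import DetectConfig
from nanomap.simgen import SimConfig
from nanomap.tracing import TraceConfig


@dataclass(frozen=True)
class FlattenConfig:
    line_order: int = 1


@dataclass
class RunConfig:
    """All stage parameters of a reproducible run."""

    seed: int = 0
    bp_per_nm: float = 2.94
    sim: SimConfig = field(default_factory=SimConfig)
    flatten: FlattenConfig = field(default_factory=FlattenConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    trace: TraceConfig = field(default_factory=TraceConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    min_area_px: int | None = None
    n_molecules: int = 10
    molecule_length_bp: int = 680
    input_dir: str | None = None
    output_dir: str | None = None

    def calibration(self) -> Calibration:
        return Calibration(self.bp_per_nm)

    def to_dict(self) -> dict:
        return _asdict_clean(self)


_NESTED = {
    "sim": SimConfig,
    "flatten": FlattenConfig,
    "segment": SegmentConfig,
    "trace": TraceConfig,
    "detect": DetectConfig,
}


def _asdict_clean(obj) -> dict:
    out = {}
    for f in fields(obj):
        v = getattr(obj, f.name)
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            out[f.name] = _asdict_clean(v)
        elif isinstance(v, tuple):
            out[f.name] = list(v)
        else:
            out[f.name] = v
    return out


def _build(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def run_config_from_dict(data: dict) -> RunConfig:
    """Build a RunConfig from a plain dict; unknown keys are rejected."""
    data = dict(data or {})
    allowed = {f.name for f in fields(RunConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _NESTED.items():
        if name in data:
            kwargs[name] = _build(cls, dict(data.pop(name) or {}))
    kwargs.update(data)
    return RunConfig(**kwargs)


def load_run_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return run_config_from_dict(data)


def save_run_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the full configuration (recorded in run outputs)."""
    canon = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
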