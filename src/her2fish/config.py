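"""Single-document YAML configuration for the whole pipeline.

The file has one block per component::

    detector:  { ... DetectorParams fields ... }
    scoring:   { ... ScoringThresholds fields ... }
    simulator: { ... GeneratorConfig fields ... }
    report:    { overlays: true, tsv: true, text: true }
    pipeline:  { crop_margin: 10, seed: 0, log_level: INFO, out_dir: null }

Unknown keys anywhere are rejected, so typos fail loudly instead of
silently running with defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .detection import DetectorParams
from .scoring import ScoringThresholds
from .synthetic import GeneratorConfig

__all__ = ["ReportFlags", "PipelineConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Malformed configuration document."""


@dataclass(frozen=True)
class ReportFlags:
    overlays: bool = True
    tsv: bool = True
    text: bool = True


def _coerce(value: Any) -> Any:
    """YAML lists become tuples (dataclass defaults use tuples throughout)."""
    if isinstance(value, list):
        return tuple(_coerce(v) for v in value)
    if isinstance(value, dict):
        # class_mixture may be written as a mapping {normal: 0.35, ...}
        return tuple((k, _coerce(v)) for k, v in value.items())
    return value


def _build(cls, section: Mapping[str, Any] | None, name: str):
    section = section or {}
    if not isinstance(section, Mapping):
        raise ConfigError(f"config block {name!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(section) - known)
    if unknown:
        raise ConfigError(f"unknown keys {unknown} in config block {name!r}")
    kwargs = {}
    for key, value in section.items():
        default = next(f for f in fields(cls) if f.name == key).default
        kwargs[key] = _coerce(value) if isinstance(default, tuple) or isinstance(value, (list, dict)) else value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config block {name!r}: {exc}") from exc


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end pipeline needs, serializable to one YAML file."""

    detector: DetectorParams = field(default_factory=DetectorParams)
    scoring: ScoringThresholds = field(default_factory=ScoringThresholds)
    simulator: GeneratorConfig = field(default_factory=GeneratorConfig)
    report: ReportFlags = field(default_factory=ReportFlags)
    crop_margin: int = 10
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.crop_margin < 0:
            raise ValueError("crop_margin must be >= 0")


_BLOCKS = {
    "detector": (DetectorParams, "detector"),
    "scoring": (ScoringThresholds, "scoring"),
    "simulator": (GeneratorConfig, "simulator"),
    "report": (ReportFlags, "report"),
}
_PIPELINE_KEYS = ("crop_margin", "seed", "log_level", "out_dir")


def config_from_dict(doc: Mapping[str, Any] | None) -> PipelineConfig:
    doc = doc or {}
    if not isinstance(doc, Mapping):
        raise ConfigError("config document must be a mapping")
    unknown = sorted(set(doc) - set(_BLOCKS) - {"pipeline"})
    if unknown:
        raise ConfigError(f"unknown top-level config blocks {unknown}")
    kwargs: dict[str, Any] = {
        name: _build(cls, doc.get(name), label) for name, (cls, label) in _BLOCKS.items()
    }
    pipe = doc.get("pipeline") or {}
    if not isinstance(pipe, Mapping):
        raise ConfigError("config block 'pipeline' must be a mapping")
    unknown = sorted(set(pipe) - set(_PIPELINE_KEYS))
    if unknown:
        raise ConfigError(f"unknown keys {unknown} in config block 'pipeline'")
    kwargs.update(pipe)
    return PipelineConfig(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; ``None`` gives all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc)


def dump_config(config: PipelineConfig, path: str | Path) -> Path:
    """Write a config back out as YAML (tuples serialised as lists)."""
    def plain(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: plain(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, tuple):
            return [plain(v) for v in obj]
        return obj

    doc = {
        "detector": plain(config.detector),
        "scoring": plain(config.scoring),
        "simulator": plain(config.simulator),
        "report": plain(config.report),
        "pipeline": {k: getattr(config, k) for k in _PIPELINE_KEYS},
    }
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path
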