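"""Pipeline configuration: one TOML file drives every stage.

The configuration round-trips losslessly (``parse(write(cfg)) == cfg``) and
unknown keys are rejected, so stale or misspelled option files fail loudly.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

from .av import AVConfig
from .optic_disc import DiscConfig
from .segmentation import LineDetectorConfig
from .widths import WidthConfig

__all__ = ["PipelineConfig", "load_config", "dump_config", "config_to_toml"]


@dataclass(frozen=True)
class QualityGateConfig:
    threshold: float = 0.48   # quality score <= threshold -> inadequate
    folds: int = 5            # CV folds for model selection when training


@dataclass(frozen=True)
class PipelineConfig:
    working_long_side: int = 1536
    seed: int = 0
    log_level: str = "INFO"
    segmentation: LineDetectorConfig = field(default_factory=LineDetectorConfig)
    quality: QualityGateConfig = field(default_factory=QualityGateConfig)
    widths: WidthConfig = field(default_factory=WidthConfig)
    av: AVConfig = field(default_factory=AVConfig)
    disc: DiscConfig = field(default_factory=DiscConfig)


def _from_dict(cls, data: dict):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        if dataclasses.is_dataclass(f.type) or (
                isinstance(f.default_factory, type) and
                dataclasses.is_dataclass(f.default_factory)):
            kwargs[key] = _from_dict(f.default_factory, value)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_fmt(v) for v in value) + "]"
    return str(value)


def config_to_toml(config: PipelineConfig) -> str:
    """Serialise a config to TOML text (scalars first, then one table per stage)."""
    lines = []
    tables = []
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if dataclasses.is_dataclass(value):
            tables.append((f.name, value))
        else:
            lines.append(f"{f.name} = {_fmt(value)}")
    for name, value in tables:
        lines.append("")
        lines.append(f"[{name}]")
        for sf in dataclasses.fields(value):
            lines.append(f"{sf.name} = {_fmt(getattr(value, sf.name))}")
    return "\n".join(lines) + "\n"


def dump_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(config_to_toml(config))


def load_config(path) -> PipelineConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return _from_dict(PipelineConfig, data)
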