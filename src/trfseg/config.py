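"""Run configuration: YAML/JSON loading with strict key validation.

A :class:`RunConfig` bundles the seed, output location and the sub-configs
of the simulation, synthetic-study and sweep modules.  Loading fills
defaults for absent fields and rejects unknown keys by name; a config
round-trips losslessly through ``to_dict``/``from_dict``.
"""

from __future__ import annotations

import dataclasses
import json
import typing
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .simulation import SimulationConfig
from .study import SweepConfig
from .synthetic import SyntheticStudyConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclasses.dataclass
class RunConfig:
    """Top-level run configuration."""

    seed: int = 0
    output_dir: str = "results"
    verbosity: str = "info"
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    synthetic: SyntheticStudyConfig = dataclasses.field(
        default_factory=SyntheticStudyConfig
    )
    sweep: SweepConfig = dataclasses.field(default_factory=SweepConfig)

    def to_dict(self) -> dict:
        return _listify(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, data: dict | None) -> "RunConfig":
        return _build(cls, data or {}, path="")


def _is_dataclass_type(tp) -> bool:
    return isinstance(tp, type) and dataclasses.is_dataclass(tp)


def _coerce(tp, value, path: str):
    origin = typing.get_origin(tp)
    if _is_dataclass_type(tp):
        if not isinstance(value, dict):
            raise ConfigError(f"expected a mapping for '{path}'")
        return _build(tp, value, path)
    if origin is tuple:
        (arg,) = set(typing.get_args(tp)) - {Ellipsis} or {float}
        if not isinstance(value, (list, tuple)):
            raise ConfigError(f"expected a list for '{path}'")
        return tuple(_coerce(arg, v, f"{path}[{i}]") for i, v in enumerate(value))
    return value


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        where = path or cls.__name__
        raise ConfigError(f"unknown configuration key '{unknown[0]}' in {where}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        tp = f.type
        if isinstance(tp, str):  # from __future__ annotations
            tp = typing.get_type_hints(cls).get(name, type(value))
        kwargs[name] = _coerce(tp, value, f"{path}.{name}".lstrip("."))
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _listify(obj):
    """Recursively turn tuples into lists (and numpy scalars into Python
    numbers) so YAML/JSON can represent them."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    if hasattr(obj, "item") and not isinstance(obj, (str, bytes)):
        return obj.item()
    return obj


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file; an empty file yields defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text) if text.strip() else {}
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root of {path} must be a mapping")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    """Write a RunConfig as YAML (JSON when the suffix is .json)."""
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, default=str))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
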