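"""Run configuration: nested sections mirroring the spec dataclasses, loaded
from YAML with defaults for every field and rejection of unknown keys."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .losses import LossWeights
from .metrics import MetricConfig
from .models import DiscriminatorSpec, GeneratorSpec
from .phantom import DegradationSpec, PhantomSpec
from .training import SplitSpec, TrainConfig

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    degradation: DegradationSpec = field(default_factory=DegradationSpec)
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)
    losses: LossWeights = field(default_factory=LossWeights)
    metrics: MetricConfig = field(default_factory=MetricConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    seed: int = 0


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in _NESTED:
            value = _build(_NESTED[f.name], value, f"{context}.{f.name}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


_NESTED = {
    "phantom": PhantomSpec,
    "degradation": DegradationSpec,
    "generator": GeneratorSpec,
    "discriminator": DiscriminatorSpec,
    "losses": LossWeights,
    "metrics": MetricConfig,
    "training": TrainConfig,
    "split": SplitSpec,
    "loss_weights": LossWeights,
}


def load_config(path: str | Path | None) -> RunConfig:
    """YAML file -> RunConfig; every field defaulted, unknown keys rejected."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    return _build(RunConfig, data, "config")


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Echo the effective configuration (reproducibility snapshot)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_listify(dataclasses.asdict(cfg)), fh, sort_keys=False)
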