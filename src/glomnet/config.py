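"""Plain-text (YAML key-value) configuration files for experiments.

A config file holds the :class:`~glomnet.network.NetworkConfig` keys plus
optional experiment-level keys ``seed``, ``sweep_weights`` and
``sweep_seeds``. Unknown keys are rejected. ``glomnet config-dump``
prints the full default schema.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .network import NetworkConfig

__all__ = ["ExperimentSettings", "load_config", "dump_default_config"]

_EXPERIMENT_KEYS = ("seed", "sweep_weights", "sweep_seeds")


@dataclasses.dataclass
class ExperimentSettings:
    network: NetworkConfig
    seed: int = 1
    sweep_weights: list = dataclasses.field(
        default_factory=lambda: list(range(0, 31)))
    sweep_seeds: list = dataclasses.field(
        default_factory=lambda: list(range(1, 11)))


def load_config(path) -> ExperimentSettings:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must be a key-value mapping")
    extra = {k: raw.pop(k) for k in list(raw) if k in _EXPERIMENT_KEYS}
    net = NetworkConfig.from_dict(raw)
    return ExperimentSettings(network=net, **extra)


def dump_default_config() -> str:
    settings = ExperimentSettings(network=NetworkConfig())
    doc = dict(settings.network.to_dict())
    doc["seed"] = settings.seed
    doc["sweep_weights"] = settings.sweep_weights
    doc["sweep_seeds"] = settings.sweep_seeds
    return yaml.safe_dump(doc, sort_keys=False)
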