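"""YAML configuration: one file carries every tunable of a simulation.

Sections map one-to-one onto the parameter dataclasses::

    device:     StdpParams        (conductances in μS, times in ns)
    variation:  VariationSpec     (levels are σ/μ)
    pulses:     PulseSpec         (volts / ns)
    encoder:    EncoderConfig
    lif:        LifConfig
    train:      TrainConfig

Missing sections or keys fall back to the defaults; unknown keys raise.
"""

from __future__ import annotations

from dataclasses import asdict, fields

import yaml

from .device import StdpParams, VariationSpec
from .encoding import EncoderConfig
from .network import LifConfig
from .training import TrainConfig
from .waveform import PulseSpec

__all__ = ["SECTIONS", "load_config", "save_config", "default_config"]

SECTIONS = {
    "device": StdpParams,
    "variation": VariationSpec,
    "pulses": PulseSpec,
    "encoder": EncoderConfig,
    "lif": LifConfig,
    "train": TrainConfig,
}


def _build(cls, payload: dict):
    valid = {f.name for f in fields(cls)}
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    if cls is VariationSpec and "varied_params" in payload:
        payload = dict(payload, varied_params=tuple(payload["varied_params"]))
    return cls(**payload)


def default_config() -> dict:
    return {name: cls() for name, cls in SECTIONS.items()}


def load_config(path) -> dict:
    """Load a YAML config into a dict of parameter dataclasses."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    unknown = set(raw) - set(SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return {
        name: _build(cls, raw.get(name, {}) or {})
        for name, cls in SECTIONS.items()
    }


def save_config(config: dict, path) -> None:
    """Write a dict of parameter dataclasses back to YAML."""
    payload = {}
    for name, obj in config.items():
        if name not in SECTIONS:
            raise ValueError(f"unknown config section: {name}")
        d = asdict(obj)
        if "varied_params" in d:
            d["varied_params"] = list(d["varied_params"])
        payload[name] = d
    with open(path, "w") as f:
        yaml.safe_dump(payload, f, sort_keys=False)
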