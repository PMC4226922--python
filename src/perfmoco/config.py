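"""Structured configuration files for the CLI.

A single YAML file with one section per module; unknown keys are rejected
so typos fail loudly. All shipped defaults are the published parameter
settings (regularization weights, knot spacings, pass limits, thresholds).
"""

from __future__ import annotations

from dataclasses import fields, replace

import yaml

from .experiments import ExperimentConfig
from .moco_icasp import IcaspConfig
from .moco_quasip import QuasipConfig
from .phantom import PhantomConfig
from .registration import RegistrationConfig

_SECTIONS = {
    "phantom": PhantomConfig,
    "icasp": IcaspConfig,
    "quasip": QuasipConfig,
}


def _apply(instance, overrides: dict, path: str):
    valid = {f.name for f in fields(instance)}
    updates = {}
    for key, value in overrides.items():
        if key not in valid:
            raise ValueError(f"unknown configuration key {path}.{key}")
        current = getattr(instance, key)
        if key == "registration" and isinstance(value, dict):
            value = _apply(current, value, f"{path}.registration")
        elif isinstance(current, tuple) and isinstance(value, list):
            value = tuple(value)
        updates[key] = value
    return replace(instance, **updates)


def load_config(path: str | None) -> ExperimentConfig:
    """Load an experiment configuration, or the defaults when no path."""
    config = ExperimentConfig()
    if path is None:
        return config
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    updates = {}
    for section, value in data.items():
        if section in _SECTIONS:
            updates[section] = _apply(getattr(config, section), value or {}, section)
        elif section in ("n_sections", "include_stress", "stress_heart_rate"):
            updates[section] = value
        else:
            raise ValueError(f"{path}: unknown section {section!r}")
    return replace(config, **updates)
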