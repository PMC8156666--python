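"""Access to packaged defaults: configuration and reference fixtures."""

from __future__ import annotations

import copy
import json
from importlib import resources
from typing import Any

import yaml

from .model_core import StateVector

__all__ = [
    "load_default_config",
    "load_config",
    "reference_steady_states",
    "reference_initial_conditions",
]


def _data_text(name: str) -> str:
    return resources.files("osteoimmune.data").joinpath(name).read_text()


def load_default_config() -> dict[str, Any]:
    """The packaged default configuration as a nested dict."""
    return yaml.safe_load(_data_text("default_config.yaml"))


def load_config(path: str | None = None) -> dict[str, Any]:
    """Load a YAML/JSON config file, filling omitted sections from defaults."""
    cfg = load_default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh)
    if user:
        cfg = _deep_update(cfg, user)
    return cfg


def _deep_update(base: dict, upd: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def _load_state_fixture(name: str, dimensionless: bool) -> dict[int, StateVector]:
    raw = json.loads(_data_text(name))
    return {
        int(k): StateVector.from_dict(v, dimensionless=dimensionless)
        for k, v in raw.items()
        if k != "description"
    }


def reference_steady_states() -> dict[int, StateVector]:
    """Built-in cluster steady states (dimensional: cells / expression units)."""
    return _load_state_fixture("reference_steady_states.json", dimensionless=False)


def reference_initial_conditions() -> dict[int, StateVector]:
    """Built-in dimensionless patient initial conditions per cluster."""
    return _load_state_fixture("reference_initial_conditions.json", dimensionless=True)
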