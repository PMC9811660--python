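"""YAML/JSON configuration loading for model parameters and region sets."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .model import BindingContext, SpinSystemParams

__all__ = ["load_params", "load_context", "load_regions"]


def _read(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return data


def load_params(path: str | Path) -> SpinSystemParams:
    """SpinSystemParams from a YAML/JSON mapping; absent keys keep defaults."""
    data = _read(path)
    allowed = {"tau_c", "proton_frequency", "linewidth_dia", "t_evol", "k_const"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return SpinSystemParams(**{k: float(v) for k, v in data.items()})


def load_context(path: str | Path) -> BindingContext:
    """BindingContext (total concentrations, molar) from YAML/JSON."""
    data = _read(path)
    allowed = {"labeled_total", "partner_total"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown context keys: {sorted(unknown)}")
    return BindingContext(**{k: float(v) for k, v in data.items()})


def load_regions(path: str | Path) -> dict[str, frozenset[int]]:
    """Region residue sets (name -> residue numbers) from YAML/JSON."""
    data = _read(path)
    return {str(k): frozenset(int(r) for r in v) for k, v in data.items()}
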