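"""Run configuration: YAML schema, validation and output manifests.

A run configuration gathers the protocol, phantom, fluctuation model and
seeds into one YAML document that round-trips losslessly.  A single
top-level seed fans out deterministically to named per-stage sub-seeds
(phantom geometry, acquisition noise, clustering, shim optimisation) so any
stage can be re-run in isolation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from .fieldcycle import FFCProtocol
from .scanner import FluctuationModel

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config", "stage_seeds"]


class ConfigError(ValueError):
    """Schema violation; the message names the offending key."""


@dataclass
class RunConfig:
    protocol: FFCProtocol = field(default_factory=FFCProtocol)
    phantom: str = "bottle"
    grid_size: int = 128
    fluctuation: FluctuationModel = field(default_factory=FluctuationModel)
    seed: int = 42
    snr: Optional[float] = 100.0
    cluster_k: int = 2
    out_dir: str = "ffc_run"
    verbosity: int = 1


_PROTOCOL_REQUIRED = ("evolution_fields", "evolution_times")


def stage_seeds(seed: int) -> Dict[str, int]:
    """Deterministic named sub-seeds derived from the top-level seed."""
    rng = np.random.default_rng(seed)
    names = ("phantom", "noise", "cluster", "tlbo")
    return {n: int(s) for n, s in zip(names, rng.integers(0, 2**31 - 1, len(names)))}


def _build(cls, section: dict, name: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    # YAML lists -> tuples for the frozen dataclasses
    kwargs = {}
    for k, v in section.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[k] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' section: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Defaults are filled for anything omitted; an explicit protocol section
    must name its evolution fields and times.  Schema violations raise
    :class:`ConfigError` naming the offending key.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    kwargs = dict(raw)
    if "protocol" in raw:
        proto = raw["protocol"]
        if not isinstance(proto, dict):
            raise ConfigError("'protocol' must be a mapping")
        for req in _PROTOCOL_REQUIRED:
            if req not in proto:
                raise ConfigError(f"protocol section missing required key '{req}'")
        kwargs["protocol"] = _build(FFCProtocol, proto, "protocol")
    if "fluctuation" in raw:
        if not isinstance(raw["fluctuation"], dict):
            raise ConfigError("'fluctuation' must be a mapping")
        kwargs["fluctuation"] = _build(FluctuationModel, raw["fluctuation"], "fluctuation")
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(config: RunConfig, path=None) -> str:
    """Serialise a RunConfig to YAML (lossless round trip)."""

    def clean(obj):
        if isinstance(obj, tuple):
            return [clean(x) for x in obj]
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        return obj

    doc = {
        **{k: v for k, v in asdict(config).items() if k not in ("protocol", "fluctuation")},
        "protocol": clean(asdict(config.protocol)),
        "fluctuation": clean(asdict(config.fluctuation)),
    }
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
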