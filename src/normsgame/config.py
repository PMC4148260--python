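"""Run configuration: flat YAML files with validated defaults.

Defaults follow the model's baseline parameter set (A=1, B=0.5, R=10,
r=0.01, no punishment); unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import SimulationParams
from .experiments import Schedule, ScheduleEntry
from .sanctioning import PunishmentConfig

__all__ = ["RunConfig", "load_config", "config_to_dict"]

_PARAM_KEYS = {f.name for f in dataclasses.fields(SimulationParams)}
_PUNISH_KEYS = {"mode", "C", "k", "C0", "direction"}
_OTHER_KEYS = {"L", "schedule", "norm_threshold", "coexist_threshold"}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one scenario."""

    params: SimulationParams = field(default_factory=SimulationParams)
    punish: PunishmentConfig = field(default_factory=PunishmentConfig)
    schedule: Schedule = field(default_factory=Schedule)
    norm_threshold: float = 0.8
    coexist_threshold: float = 0.8


def _build(data: dict) -> RunConfig:
    unknown = set(data) - _PARAM_KEYS - _PUNISH_KEYS - _OTHER_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    p_kwargs = {k: v for k, v in data.items() if k in _PARAM_KEYS}
    pu_kwargs = {k: v for k, v in data.items() if k in _PUNISH_KEYS}
    if "L" in data:
        if "C" in data:
            raise ValueError("give either C or the punishment level L, not both")
        k = pu_kwargs.get("k", 3.0)
        pu_kwargs["C"] = float(data["L"]) / (k + 1.0)
    try:
        params = SimulationParams(**p_kwargs)
        punish = PunishmentConfig(**pu_kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
    entries = []
    for item in data.get("schedule") or []:
        try:
            entries.append(
                ScheduleEntry(
                    t0=int(item["t0"]),
                    param=str(item["param"]),
                    value=float(item["value"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"invalid schedule entry {item!r}: {exc}") from exc
    return RunConfig(
        params=params,
        punish=punish,
        schedule=Schedule(tuple(entries)),
        norm_threshold=float(data.get("norm_threshold", 0.8)),
        coexist_threshold=float(data.get("coexist_threshold", 0.8)),
    )


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config (defaults when path is None or the file is
    empty), then apply flat-key overrides."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"configuration {path} must be a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return _build(data)


def config_to_dict(cfg: RunConfig) -> dict:
    """Flat dict of the fully resolved configuration (for provenance
    logging next to every output file)."""
    out = dataclasses.asdict(cfg.params)
    out.update(dataclasses.asdict(cfg.punish))
    out["L"] = cfg.punish.L
    out["schedule"] = [dataclasses.asdict(e) for e in cfg.schedule.entries]
    out["norm_threshold"] = cfg.norm_threshold
    out["coexist_threshold"] = cfg.coexist_threshold
    return out
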