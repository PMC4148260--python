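"""Writers and readers for snapshots, time series, event logs, diagrams.

A grid snapshot is a plain CSV matrix of integer codes
``2*(preference-1) + (behavior-1)`` in {0, 1, 2, 3} — the four visual
states of the model (population-1/2 member showing behavior 1/2) — with
a JSON sidecar (``<path>.meta.json``) holding t, the resolved parameters
and the payoff arrays, so that a snapshot round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GridState, SimulationParams

__all__ = [
    "encode_snapshot",
    "decode_snapshot",
    "write_snapshot",
    "read_snapshot",
    "write_timeseries",
    "write_events",
    "write_phase_diagram",
]

TIMESERIES_COLUMNS = [
    "t",
    "share_b1",
    "share_b2",
    "share_preferred",
    "mean_payoff",
    "frac_sincere_punishers",
    "frac_hypocritical_punishers",
]


def encode_snapshot(state: GridState) -> np.ndarray:
    """Integer codes 2*(preference-1) + (behavior-1) per site."""
    return (2 * (state.preference.astype(int) - 1) + (state.behavior.astype(int) - 1))


def decode_snapshot(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`encode_snapshot` -> (preference, behavior)."""
    if codes.min() < 0 or codes.max() > 3:
        raise ValueError("snapshot codes must lie in {0, 1, 2, 3}")
    pref = (codes // 2 + 1).astype(np.int8)
    beh = (codes % 2 + 1).astype(np.int8)
    return pref, beh


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_snapshot(
    state: GridState, path: str | Path, params: SimulationParams | None = None
) -> None:
    path = Path(path)
    codes = encode_snapshot(state)
    np.savetxt(path, codes, fmt="%d", delimiter=",")
    meta = {
        "t": int(state.t),
        "last_payoff": state.last_payoff.tolist(),
        "cumulative_payoff": state.cumulative_payoff.tolist(),
    }
    if params is not None:
        meta["params"] = dataclasses.asdict(params)
    _sidecar(path).write_text(json.dumps(meta))


def read_snapshot(path: str | Path) -> GridState:
    path = Path(path)
    try:
        codes = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed snapshot {path}: {exc}") from exc
    pref, beh = decode_snapshot(codes)
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        t = int(meta["t"])
        last = np.asarray(meta["last_payoff"], dtype=float)
        cum = np.asarray(meta["cumulative_payoff"], dtype=float)
    else:
        t = 0
        last = np.zeros(codes.shape)
        cum = np.zeros(codes.shape)
    return GridState(
        preference=pref, behavior=beh, last_payoff=last,
        cumulative_payoff=cum, t=t,
    )


def write_timeseries(ts: pd.DataFrame, path: str | Path, n_agents: int) -> None:
    """Time-series CSV with the documented column set."""
    out = pd.DataFrame()
    out["t"] = ts["t"].astype(int)
    out["share_b1"] = ts["share_b1"]
    out["share_b2"] = ts["share_b2"]
    out["share_preferred"] = ts["share_preferred"]
    out["mean_payoff"] = ts["mean_payoff"]
    out["frac_sincere_punishers"] = ts["n_punishers_sincere"] / n_agents
    out["frac_hypocritical_punishers"] = ts["n_punishers_hypocritical"] / n_agents
    out.to_csv(path, index=False)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def write_phase_diagram(diagram, path: str | Path) -> None:
    diagram.to_dataframe().to_csv(path, index=False)
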