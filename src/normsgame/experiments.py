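"""Scenario engine: runs, outcome classification, sweeps, schedules.

`run_simulation` is the main entry point: it initializes a lattice,
advances it with the JIT engine (or the pure-Python reference engine)
and returns per-step metrics, the final grid, and the sanction log.
`phase_sweep` maps parameter grids to majority outcome labels over
independent replicates, reproducing the model's phase diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _engine
from .core import GridState, SimulationParams, init_grid, neighborhood_offsets
from .meanfield import COEXISTENCE, NORM1, NORM2
from .sanctioning import MODE_CODES, PunishmentConfig

__all__ = [
    "ScheduleEntry",
    "Schedule",
    "SimulationResult",
    "PhaseDiagram",
    "run_simulation",
    "classify_outcome",
    "classify_shares",
    "local_conformity",
    "phase_sweep",
    "punisher_proportions",
]

_SCHEDULABLE = {"r": _engine.SCHED_R, "C": _engine.SCHED_C, "C0": _engine.SCHED_C0}


@dataclass(frozen=True)
class ScheduleEntry:
    """Set ``param`` to ``value`` at the start of step ``t0``."""

    t0: int
    param: str
    value: float

    def __post_init__(self) -> None:
        if self.param not in _SCHEDULABLE:
            raise ValueError(
                f"parameter {self.param!r} is not schedulable; "
                f"only punishment parameters and r are: {sorted(_SCHEDULABLE)}"
            )
        if self.t0 < 0:
            raise ValueError("t0 must be non-negative")


@dataclass(frozen=True)
class Schedule:
    """Ordered list of in-run parameter changes (e.g. dropping the
    maximum punishment level C0 after a norm has formed)."""

    entries: tuple[ScheduleEntry, ...] = ()

    def __post_init__(self) -> None:
        entries = tuple(
            e if isinstance(e, ScheduleEntry) else ScheduleEntry(*e)
            for e in self.entries
        )
        object.__setattr__(self, "entries", entries)
        times = [e.t0 for e in entries]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("schedule times t0 must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = np.array([e.t0 for e in self.entries], dtype=np.int64)
        code = np.array(
            [_SCHEDULABLE[e.param] for e in self.entries], dtype=np.int64
        )
        val = np.array([e.value for e in self.entries])
        return t, code, val


@dataclass
class SimulationResult:
    """Output of one simulation run."""

    params: SimulationParams
    punish: PunishmentConfig
    schedule: Schedule
    seed: int
    timeseries: pd.DataFrame
    state: GridState
    events: pd.DataFrame
    t_final: int
    stopped_early: bool
    totals: dict[str, float] = field(default_factory=dict)

    def tail_means(self, window: int = 10) -> pd.Series:
        """Mean of the last ``window`` recorded steps of the time series."""
        return self.timeseries.tail(window).mean()


def _derive_seeds(seed: int) -> tuple[np.random.Generator, int]:
    ss = np.random.SeedSequence(seed)
    s_init, s_dyn = ss.spawn(2)
    kernel_seed = int(s_dyn.generate_state(1)[0] % np.uint32(2**31 - 1)) + 1
    return np.random.default_rng(s_init), kernel_seed


def run_simulation(
    params: SimulationParams,
    punish: PunishmentConfig | None = None,
    schedule: Schedule | None = None,
    seed: int | None = None,
    stop_threshold: float | None = None,
    record_events: bool = False,
    max_events: int = 2_000_000,
    engine: str = "numba",
) -> SimulationResult:
    """Run one scenario, deterministic given ``seed``.

    Parameters
    ----------
    stop_threshold : float, optional
        If given, the run stops as soon as one behavior is displayed by
        at least this fraction of agents (checked at step ends).
    record_events : bool
        Record the full sanction log (capped at ``max_events``); per-step
        sanction counts are always recorded in the time series.
    engine : str
        ``"numba"`` (default, JIT kernel) or ``"python"`` (readable
        reference implementation in :mod:`normsgame.dynamics`).
    """
    punish = punish or PunishmentConfig()
    schedule = schedule or Schedule()
    if seed is None:
        seed = params.seed
    init_rng, kernel_seed = _derive_seeds(seed)
    state = init_grid(params, init_rng)

    if engine == "numba":
        return _run_numba(
            params, punish, schedule, seed, kernel_seed, state,
            stop_threshold, record_events, max_events,
        )
    if engine == "python":
        return _run_python(
            params, punish, schedule, seed, kernel_seed, state,
            stop_threshold, record_events,
        )
    raise ValueError(f"unknown engine {engine!r}")


def _events_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=[
            "t",
            "punisher_row",
            "punisher_col",
            "punishee_row",
            "punishee_col",
            "mode",
            "label",
            "cost",
            "fine",
            "punisher_behavior",
            "punishee_behavior",
        ],
    )


def _run_numba(
    params, punish, schedule, seed, kernel_seed, state,
    stop_threshold, record_events, max_events,
) -> SimulationResult:
    offsets = np.ascontiguousarray(
        neighborhood_offsets(params.R, params.metric)
    )
    sched_t, sched_code, sched_val = schedule.as_arrays()
    pref = np.ascontiguousarray(state.preference.ravel())
    beh = np.ascontiguousarray(state.behavior.ravel())
    (
        metrics, last_pay, cum_pay, t_final,
        ev_int, ev_flt, n_events, totals,
    ) = _engine.run_kernel(
        pref,
        beh,
        params.n_rows,
        params.n_cols,
        offsets,
        float(params.A),
        float(params.B),
        float(params.r),
        int(params.T),
        MODE_CODES[punish.mode],
        float(punish.C),
        float(punish.k),
        float(punish.C0),
        punish.direction == "mutual",
        params.noise_scope == "all",
        sched_t,
        sched_code,
        sched_val,
        float(stop_threshold or 0.0),
        kernel_seed,
        record_events,
        max_events,
    )
    dims = params.dims
    final = GridState(
        preference=pref.reshape(dims),
        behavior=beh.reshape(dims),
        last_payoff=last_pay.reshape(dims),
        cumulative_payoff=cum_pay.reshape(dims),
        t=int(t_final),
    )
    ts = pd.DataFrame(metrics, columns=list(_engine.METRIC_COLUMNS))
    ts.insert(0, "t", np.arange(1, t_final + 1))
    ts["share_b2"] = 1.0 - ts["share_b1"]
    n_cols = params.n_cols
    ev_rows = [
        (
            int(ev_int[i, 0]),
            int(ev_int[i, 1]) // n_cols,
            int(ev_int[i, 1]) % n_cols,
            int(ev_int[i, 2]) // n_cols,
            int(ev_int[i, 2]) % n_cols,
            punish.mode,
            "hypocritical" if ev_int[i, 3] else "sincere",
            float(ev_flt[i, 0]),
            float(ev_flt[i, 1]),
            int(ev_int[i, 4]),
            int(ev_int[i, 5]),
        )
        for i in range(n_events)
    ]
    return SimulationResult(
        params=params,
        punish=punish,
        schedule=schedule,
        seed=seed,
        timeseries=ts,
        state=final,
        events=_events_frame(ev_rows),
        t_final=int(t_final),
        stopped_early=int(t_final) < params.T,
        totals={
            "gross_payoff": float(totals[0]),
            "cost_paid": float(totals[1]),
            "fine_imposed": float(totals[2]),
        },
    )


def _run_python(
    params, punish, schedule, seed, kernel_seed, state,
    stop_threshold, record_events,
) -> SimulationResult:
    from .dynamics import advance_step

    rng = np.random.default_rng(kernel_seed)
    sched = {e.t0: e for e in schedule.entries}
    rows = []
    ev_rows: list = []
    events = [] if record_events else None
    stopped = False
    for t in range(params.T):
        if t in sched:
            e = sched[t]
            if e.param == "r":
                params = replace(params, r=e.value)
            else:
                punish = replace(punish, **{e.param: e.value})
        n0 = len(events) if events is not None else 0
        sm = advance_step(state, params, punish, rng, events)
        rows.append(
            (
                sm.t,
                sm.share_b1,
                sm.share_preferred,
                sm.mean_payoff,
                sm.n_sanctions_sincere,
                sm.n_sanctions_hypocritical,
                np.nan,
                np.nan,
                1.0 - sm.share_b1,
            )
        )
        if events is not None:
            for e in events[n0:]:
                ev_rows.append(
                    (
                        sm.t,
                        e.punisher.row,
                        e.punisher.col,
                        e.punishee.row,
                        e.punishee.col,
                        e.mode,
                        e.label,
                        e.cost_paid,
                        e.fine_imposed,
                        e.punisher_behavior,
                        e.punishee_behavior,
                    )
                )
        if stop_threshold and (
            sm.share_b1 >= stop_threshold or 1 - sm.share_b1 >= stop_threshold
        ):
            stopped = True
            break
    ts = pd.DataFrame(
        rows,
        columns=["t"] + list(_engine.METRIC_COLUMNS) + ["share_b2"],
    )
    return SimulationResult(
        params=params,
        punish=punish,
        schedule=schedule,
        seed=seed,
        timeseries=ts,
        state=state,
        events=_events_frame(ev_rows),
        t_final=state.t,
        stopped_early=stopped,
        totals={},
    )


def classify_shares(
    share_b1: float,
    share_b2: float,
    share_preferred: float,
    norm_threshold: float = 0.8,
    coexist_threshold: float = 0.8,
) -> str:
    """Outcome label from aggregate shares.

    norm1/norm2 when one behavior is displayed by at least
    ``norm_threshold`` of agents; coexistence when at least
    ``coexist_threshold`` display their own preferred behavior;
    otherwise the label of the largest of the three shares (ties favor
    coexistence)."""
    for thr, name in ((norm_threshold, "norm"), (coexist_threshold, "coexist")):
        if not 0.5 < thr <= 1.0:
            raise ValueError(f"{name} threshold must lie in (0.5, 1]")
    if share_b1 >= norm_threshold:
        return NORM1
    if share_b2 >= norm_threshold:
        return NORM2
    if share_preferred >= coexist_threshold:
        return COEXISTENCE
    best = max(share_b1, share_b2, share_preferred)
    if share_preferred == best:
        return COEXISTENCE
    return NORM1 if share_b1 >= share_b2 else NORM2


def classify_outcome(
    state: GridState,
    norm_threshold: float = 0.8,
    coexist_threshold: float = 0.8,
) -> str:
    """Outcome label of a grid state (see :func:`classify_shares`)."""
    return classify_shares(
        state.share_b1,
        state.share_b2,
        state.share_preferred,
        norm_threshold,
        coexist_threshold,
    )


def classify_result(
    result: SimulationResult,
    norm_threshold: float = 0.8,
    coexist_threshold: float = 0.8,
    average_last: int = 1,
) -> str:
    """Outcome label of a run, optionally time-averaged over the final
    ``average_last`` steps to damp noise."""
    if average_last <= 1:
        return classify_outcome(result.state, norm_threshold, coexist_threshold)
    tail = result.tail_means(average_last)
    return classify_shares(
        tail["share_b1"],
        tail["share_b2"],
        tail["share_preferred"],
        norm_threshold,
        coexist_threshold,
    )


def local_conformity(state: GridState, R: int, metric: str = "chebyshev") -> float:
    """Mean over agents of the fraction of range-R neighbors displaying
    the agent's own behavior (local-consensus order parameter)."""
    offs = neighborhood_offsets(R, metric)
    beh = state.behavior
    same = np.zeros(beh.shape)
    for dr, dc in offs:
        same += beh == np.roll(np.roll(beh, -dr, axis=0), -dc, axis=1)
    return float(np.mean(same / len(offs)))


@dataclass
class PhaseDiagram:
    """Replicated outcome labels on a 2-D parameter grid."""

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    counts: np.ndarray  # (n1, n2, 3) counts in label order (norm1, norm2, coexistence)
    replicates: int

    LABEL_ORDER = (NORM1, NORM2, COEXISTENCE)

    @property
    def majority_label(self) -> np.ndarray:
        idx = self.counts.argmax(axis=2)
        return np.array(self.LABEL_ORDER, dtype=object)[idx]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, v1 in enumerate(self.axis1_values):
            for j, v2 in enumerate(self.axis2_values):
                for li, lab in enumerate(self.LABEL_ORDER):
                    rows.append((v1, v2, lab, int(self.counts[i, j, li])))
        return pd.DataFrame(
            rows, columns=[self.axis1_name, self.axis2_name, "label", "count"]
        )


def _cell_seed(base_seed: int, i: int, j: int, rep: int) -> int:
    ss = np.random.SeedSequence((base_seed, i, j, rep))
    return int(ss.generate_state(1)[0] % np.uint32(2**31 - 1)) + 1


def _with_param(params: SimulationParams, punish: PunishmentConfig, name: str, value):
    """Set an axis parameter on whichever config owns it; "L" sweeps the
    punishment level at fixed k."""
    if name == "L":
        return params, replace(punish, C=value / (punish.k + 1.0))
    if hasattr(punish, name) and name in ("C", "k", "C0"):
        return params, replace(punish, **{name: value})
    if hasattr(params, name):
        if name == "R":
            value = int(value)
        return replace(params, **{name: value}), punish
    raise ValueError(f"unknown sweep parameter {name!r}")


def phase_sweep(
    base_params: SimulationParams,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    replicates: int = 5,
    steps: int | None = None,
    seed: int = 0,
    punish: PunishmentConfig | None = None,
    norm_threshold: float = 0.8,
    coexist_threshold: float = 0.8,
    average_last: int = 10,
    stop_threshold: float | None = None,
) -> PhaseDiagram:
    """Majority outcome label per cell of a 2-D parameter grid.

    Each cell runs ``replicates`` independent simulations with seeds
    derived deterministically from ``seed`` and the cell indices.
    """
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    punish = punish or PunishmentConfig()
    name1, vals1 = axis1
    name2, vals2 = axis2
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    if vals1.size == 0 or vals2.size == 0:
        raise ValueError("axis value grids must be non-empty")
    if steps is not None:
        base_params = replace(base_params, T=steps)
    counts = np.zeros((vals1.size, vals2.size, 3), dtype=int)
    lab_idx = {lab: li for li, lab in enumerate(PhaseDiagram.LABEL_ORDER)}
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            p, pc = _with_param(base_params, punish, name1, v1)
            p, pc = _with_param(p, pc, name2, v2)
            for rep in range(replicates):
                res = run_simulation(
                    p,
                    punish=pc,
                    seed=_cell_seed(seed, i, j, rep),
                    stop_threshold=stop_threshold,
                )
                lab = classify_result(
                    res, norm_threshold, coexist_threshold, average_last
                )
                counts[i, j, lab_idx[lab]] += 1
    return PhaseDiagram(name1, vals1, name2, vals2, counts, replicates)


def deviant_sanction_ratio(
    events: pd.DataFrame, deviant_behavior: int, t_min: int = 0
) -> float:
    """Sincere:hypocritical ratio among sanctions imposed *on* agents
    displaying ``deviant_behavior`` from step ``t_min`` on.

    After a norm has fixed, this isolates punishment of the residual
    norm deviants (under behavior-based rules the deviants themselves
    also trigger sanctions against conformists, a reverse flow that this
    ratio deliberately excludes). Once population 2 has assimilated, the
    punishers of deviants are a representative draw of the local
    population mix, so the ratio is expected to approach S:(1-S).
    """
    w = events[(events["t"] >= t_min) & (events["punishee_behavior"] == deviant_behavior)]
    n_sin = int((w["label"] == "sincere").sum())
    n_hyp = int((w["label"] == "hypocritical").sum())
    if n_hyp == 0:
        return float("inf") if n_sin else float("nan")
    return n_sin / n_hyp


def punisher_proportions(
    events: pd.DataFrame,
    window: int,
    n_agents: int,
    t_max: int | None = None,
) -> pd.DataFrame:
    """Windowed sanction statistics from an event log.

    For each window of ``window`` steps: the fraction of sanction events
    labeled sincere/hypocritical, and the fraction of all agents that
    punished at least once (sincerely / hypocritically) within the
    window. Windows without events report zero fractions.
    """
    if window < 1:
        raise ValueError("window must be at least 1")
    if t_max is None:
        t_max = int(events["t"].max()) if len(events) else window
    rows = []
    for start in range(1, t_max + 1, window):
        end = min(start + window - 1, t_max)
        w = events[(events["t"] >= start) & (events["t"] <= end)]
        n_ev = len(w)
        sin = w[w["label"] == "sincere"]
        hyp = w[w["label"] == "hypocritical"]
        sin_agents = set(zip(sin["punisher_row"], sin["punisher_col"]))
        hyp_agents = set(zip(hyp["punisher_row"], hyp["punisher_col"]))
        rows.append(
            (
                start,
                end,
                n_ev,
                len(sin) / n_ev if n_ev else 0.0,
                len(hyp) / n_ev if n_ev else 0.0,
                len(sin_agents) / n_agents,
                len(hyp_agents) / n_agents,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "t_start",
            "t_end",
            "n_events",
            "frac_events_sincere",
            "frac_events_hypocritical",
            "frac_agents_sincere",
            "frac_agents_hypocritical",
        ],
    )
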