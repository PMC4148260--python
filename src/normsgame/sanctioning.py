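"""Costly peer punishment: triggers, costs, classification, accounting.

Three modes are supported. *Behavior-based* punishment targets a partner
whose displayed behavior differs from the punisher's displayed behavior;
*preference-based* punishment targets a partner whose displayed behavior
differs from the punisher's private preference; *adaptive* punishment is
behavior-based with a cost that grows as the local frequency N of
non-conforming behavior falls (group pressure exerted by local
majorities).

A punisher pays cost C and the punishee receives a fine F = k*C with
k > 1; the combined severity L = (k+1)*C is the punishment level. Agents
never punish if doing so would push their cumulative payoff negative.

Every executed sanction is classified *sincere* or *hypocritical*:
hypocritical punishers sanction what actually conforms to their own
preference (behavior-based/adaptive modes) or to their own displayed
behavior (preference-based mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GridState, Site, SimulationParams, neighborhood

__all__ = [
    "PunishmentConfig",
    "PunishmentEvent",
    "punish_decision",
    "adaptive_cost",
    "nonconforming_fraction",
    "classify_punishment",
    "apply_punishment",
]

MODES = ("none", "behavior", "preference", "adaptive")
MODE_CODES = {m: i for i, m in enumerate(MODES)}


@dataclass(frozen=True)
class PunishmentConfig:
    """Sanctioning mode and severity.

    ``C`` is the punisher's cost in the constant modes; ``C0`` is the
    maximum punishment level of the adaptive mode; ``k`` the fine
    multiplier (F = k*C, k > 1). ``direction`` controls whether only the
    focal agent may sanction or both interaction partners evaluate
    punishing each other (default).
    """

    mode: str = "none"
    C: float = 0.0
    k: float = 3.0
    C0: float = 0.0
    direction: str = "mutual"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown punishment mode {self.mode!r}")
        if self.C < 0 or self.C0 < 0:
            raise ValueError("C and C0 must be non-negative")
        if self.mode != "none" and not self.k > 1:
            raise ValueError(f"fine multiplier k must exceed 1, got {self.k}")
        if self.direction not in ("mutual", "focal-only"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def L(self) -> float:
        """Punishment level (k+1)*C."""
        return (self.k + 1.0) * self.C

    @property
    def F(self) -> float:
        """Punishment fine k*C (constant modes)."""
        return self.k * self.C

    @classmethod
    def from_level(cls, mode: str, L: float, k: float = 3.0, **kwargs) -> "PunishmentConfig":
        """Build a config from a punishment level L, holding k fixed
        (C = L/(k+1))."""
        return cls(mode=mode, C=L / (k + 1.0), k=k, **kwargs)

    @property
    def enabled(self) -> bool:
        return self.mode != "none"


@dataclass(frozen=True)
class PunishmentEvent:
    """One executed sanction.

    ``punisher_behavior``/``punishee_behavior`` snapshot the displayed
    behaviors at sanction time, so event logs can separate punishment of
    norm deviants from the reverse flow (deviants sanctioning
    conformists, which also triggers under behavior-based rules).
    """

    t: int
    punisher: Site
    punishee: Site
    mode: str
    label: str  # "sincere" or "hypocritical"
    cost_paid: float
    fine_imposed: float
    punisher_behavior: int = 0
    punishee_behavior: int = 0


def adaptive_cost(nonconform_frac: float, C0: float) -> float:
    """Group-pressure punishment cost C(N) = C0*(1-N)^4*[2-(1-N)^2]^2.

    N is the relative frequency of non-conforming behavior within the
    punisher's interaction range. The cost is C0 at N=0 (full local
    conformity), 0 at N=1, and strictly decreasing in between: local
    majorities sanction hard, local minorities barely at all.
    """
    if not 0.0 <= nonconform_frac <= 1.0:
        raise ValueError(f"nonconform_frac must lie in [0, 1], got {nonconform_frac}")
    u = 1.0 - nonconform_frac
    return C0 * u**4 * (2.0 - u * u) ** 2


def nonconforming_fraction(
    state: GridState, ego: Site, R: int, metric: str = "chebyshev"
) -> float:
    """Fraction of ego's range-R neighbors (self excluded) whose displayed
    behavior differs from ego's displayed behavior."""
    b_ego = state.behavior[ego.row, ego.col]
    nbrs = neighborhood(ego, R, state.dims, metric)
    diff = sum(1 for s in nbrs if state.behavior[s.row, s.col] != b_ego)
    return diff / len(nbrs)


def punish_decision(
    state: GridState,
    ego: Site,
    alter: Site,
    cfg: PunishmentConfig,
    params: SimulationParams,
) -> tuple[bool, float]:
    """Decide whether ego sanctions alter, returning (trigger, cost).

    Behavior mode triggers on differing displayed behaviors, preference
    mode on alter violating ego's preference; adaptive mode is
    behavior-triggered with cost from :func:`adaptive_cost` evaluated on
    ego's neighborhood. In every mode the sanction is vetoed when ego's
    cumulative payoff (before this round's interaction payoff) could not
    cover the cost.
    """
    if not cfg.enabled:
        return False, 0.0
    b_ego = state.behavior[ego.row, ego.col]
    b_alt = state.behavior[alter.row, alter.col]
    if cfg.mode == "preference":
        trigger = b_alt != state.preference[ego.row, ego.col]
        cost = cfg.C
    elif cfg.mode == "behavior":
        trigger = b_alt != b_ego
        cost = cfg.C
    else:  # adaptive
        trigger = b_alt != b_ego
        cost = adaptive_cost(
            nonconforming_fraction(state, ego, params.R, params.metric), cfg.C0
        )
    if trigger and state.cumulative_payoff[ego.row, ego.col] - cost < 0:
        trigger = False
    return trigger, cost


def classify_punishment(
    state: GridState, ego: Site, alter: Site, mode: str
) -> str:
    """Label an executed sanction sincere or hypocritical.

    Behavior-based (and adaptive) sanctions are hypocritical when the
    punished behavior is what ego privately prefers; preference-based
    sanctions are hypocritical when ego itself displays the punished
    behavior.
    """
    b_alt = state.behavior[alter.row, alter.col]
    if mode == "preference":
        hyp = b_alt == state.behavior[ego.row, ego.col]
    else:
        hyp = b_alt == state.preference[ego.row, ego.col]
    return "hypocritical" if hyp else "sincere"


def apply_punishment(
    round_payoffs: dict[Site, float],
    state: GridState,
    ego: Site,
    alter: Site,
    cost: float,
    fine: float,
) -> None:
    """Deduct ego's cost and alter's fine from this round's payoffs and
    from cumulative payoffs. Fines may drive payoffs negative; only the
    punisher-side guard exists."""
    round_payoffs[ego] -= cost
    round_payoffs[alter] -= fine
    state.cumulative_payoff[ego.row, ego.col] -= cost
    state.cumulative_payoff[alter.row, alter.col] -= fine
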