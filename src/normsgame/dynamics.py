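"""Random-sequential update: interaction, in-group imitation, noise.

One simulation step updates N/2 randomly drawn focal agents and their
interaction partners (N agents in total), then advances the clock by 1.
Each round consists of

(a) *interaction*: a focal agent and a partner within range R earn the
    pairwise payoffs, possibly modified by sanctions;
(b) *imitation*: focal and partner each draw a role model among
    same-preference neighbors and adopt its behavior with probability
    proportional to the payoff difference (proportionality 1/(A+B),
    clipped to 1), if the model's last interaction paid more;
(c) *randomization*: each updated agent flips to the opposite behavior
    with probability r.

This module is the readable reference implementation, operating one
agent at a time; production runs use the JIT engine in
:mod:`normsgame._engine`, which implements the identical update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GridState, Site, SimulationParams, neighborhood, payoff_pair
from .sanctioning import (
    PunishmentConfig,
    PunishmentEvent,
    apply_punishment,
    classify_punishment,
    punish_decision,
)

__all__ = [
    "StepMetrics",
    "choose_partner",
    "choose_role_model",
    "interaction_update",
    "imitation_update",
    "noise_update",
    "advance_step",
]


@dataclass(frozen=True)
class StepMetrics:
    """Per-step aggregates recomputed from the full grid."""

    t: int
    share_b1: float
    share_preferred: float
    mean_payoff: float
    n_sanctions_sincere: int = 0
    n_sanctions_hypocritical: int = 0


def choose_partner(
    state: GridState, focal: Site, R: int, rng: np.random.Generator,
    metric: str = "chebyshev",
) -> Site:
    """Uniform draw over the range-R neighborhood of the focal agent."""
    nbrs = neighborhood(focal, R, state.dims, metric)
    return nbrs[rng.integers(len(nbrs))]


def choose_role_model(
    state: GridState, focal: Site, R: int, rng: np.random.Generator,
    metric: str = "chebyshev",
) -> Site | None:
    """Uniform draw over same-preference neighbors within range R, or
    None when no neighbor shares the focal agent's preference."""
    p = state.preference[focal.row, focal.col]
    cands = [
        s
        for s in neighborhood(focal, R, state.dims, metric)
        if state.preference[s.row, s.col] == p
    ]
    if not cands:
        return None
    return cands[rng.integers(len(cands))]


def interaction_update(
    state: GridState,
    focal: Site,
    partner: Site,
    params: SimulationParams,
    punish_cfg: PunishmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[PunishmentEvent]:
    """Play the pairwise game, apply sanctions, settle payoffs.

    Sets each agent's ``last_payoff`` to its net payoff (matrix payoff
    minus punishment cost paid minus fine received) and adds the same
    net amount to ``cumulative_payoff``. Under mutual punishment both
    partners evaluate sanctioning sequentially (focal first); the second
    punisher's budget guard sees any fine it just received.
    """
    if focal == partner:
        raise ValueError("focal and partner must differ")
    bf = int(state.behavior[focal.row, focal.col])
    bp = int(state.behavior[partner.row, partner.col])
    pf = int(state.preference[focal.row, focal.col])
    pp = int(state.preference[partner.row, partner.col])
    gross = {
        focal: payoff_pair(bf, bp, pf, params),
        partner: payoff_pair(bp, bf, pp, params),
    }
    net = dict(gross)

    events: list[PunishmentEvent] = []
    if punish_cfg is not None and punish_cfg.enabled:
        pairs = [(focal, partner)]
        if punish_cfg.direction == "mutual":
            pairs.append((partner, focal))
        for ego, alter in pairs:
            trigger, cost = punish_decision(state, ego, alter, punish_cfg, params)
            if trigger:
                fine = punish_cfg.k * cost
                apply_punishment(net, state, ego, alter, cost, fine)
                events.append(
                    PunishmentEvent(
                        t=state.t,
                        punisher=ego,
                        punishee=alter,
                        mode=punish_cfg.mode,
                        label=classify_punishment(state, ego, alter, punish_cfg.mode),
                        cost_paid=cost,
                        fine_imposed=fine,
                        punisher_behavior=int(state.behavior[ego.row, ego.col]),
                        punishee_behavior=int(state.behavior[alter.row, alter.col]),
                    )
                )

    for site in (focal, partner):
        state.last_payoff[site.row, site.col] = net[site]
        # apply_punishment already charged the sanction flows to
        # cumulative_payoff, so only the matrix payoff is added here
        state.cumulative_payoff[site.row, site.col] += gross[site]
    return events


def imitation_update(
    state: GridState,
    agent: Site,
    role_model: Site | None,
    params: SimulationParams,
    rng: np.random.Generator,
) -> bool:
    """Proportional imitation of a same-preference role model.

    The agent adopts the model's current behavior with probability
    ``min(1, (P_model - P_agent)/(A+B))`` when the model's last
    interaction paid strictly more; ties and worse models never trigger
    imitation. Returns True when the behavior changed.
    """
    if role_model is None:
        return False
    diff = (
        state.last_payoff[role_model.row, role_model.col]
        - state.last_payoff[agent.row, agent.col]
    )
    if diff <= 0:
        return False
    prob = min(1.0, diff / (params.A + params.B))
    if rng.random() < prob:
        new = state.behavior[role_model.row, role_model.col]
        changed = new != state.behavior[agent.row, agent.col]
        state.behavior[agent.row, agent.col] = new
        return bool(changed)
    return False


def noise_update(
    state: GridState, agent: Site, r: float, rng: np.random.Generator
) -> bool:
    """With probability r the agent flips to the opposite behavior;
    the preference is untouched. Returns True when a flip occurred."""
    if rng.random() < r:
        i, j = agent.row, agent.col
        state.behavior[i, j] = 3 - state.behavior[i, j]
        return True
    return False


def advance_step(
    state: GridState,
    params: SimulationParams,
    punish_cfg: PunishmentConfig | None = None,
    rng: np.random.Generator | None = None,
    events: list[PunishmentEvent] | None = None,
) -> StepMetrics:
    """Run ``floor(N/2)`` update rounds, advance t by 1 and return metrics.

    Each round draws a focal agent uniformly with replacement, draws its
    partner, plays the interaction, then applies imitation (focal, then
    partner) and noise (focal, then partner).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_rows, n_cols = state.dims
    n = state.n_agents
    n_sin = n_hyp = 0
    for _ in range(n // 2):
        f = rng.integers(n)
        focal = Site(f // n_cols, f % n_cols)
        partner = choose_partner(state, focal, params.R, rng, params.metric)
        evs = interaction_update(state, focal, partner, params, punish_cfg, rng)
        for e in evs:
            if e.label == "sincere":
                n_sin += 1
            else:
                n_hyp += 1
        if events is not None:
            events.extend(evs)
        for agent in (focal, partner):
            model = choose_role_model(state, agent, params.R, rng, params.metric)
            imitation_update(state, agent, model, params, rng)
        if params.noise_scope == "pair":
            for agent in (focal, partner):
                noise_update(state, agent, params.r, rng)
    if params.noise_scope == "all":
        flips = rng.random(state.behavior.shape) < params.r
        state.behavior[flips] = 3 - state.behavior[flips]
    state.t += 1
    return StepMetrics(
        t=state.t,
        share_b1=state.share_b1,
        share_preferred=state.share_preferred,
        mean_payoff=float(state.last_payoff.mean()),
        n_sanctions_sincere=n_sin,
        n_sanctions_hypocritical=n_hyp,
    )
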