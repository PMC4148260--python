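"""Named scenario presets covering the model's canonical regimes.

Each entry is a flat config dict (see :mod:`normsgame.config`); grid
sizes and horizons are package defaults, since the regimes are defined
by the payoff/punishment parameters, not the lattice size.
"""

from __future__ import annotations

FIGURE_SCENARIOS: dict[str, dict] = {
    # path dependence at equal strength (baseline A=1, B=0.5, R=10, r=0.01)
    "fig1a": {"S": 0.5, "p1": 0.9, "p2": 0.4, "A": 1.0, "B": 0.5, "R": 10, "r": 0.01},
    "fig1b": {"S": 0.5, "p1": 0.4, "p2": 0.9, "A": 1.0, "B": 0.5, "R": 10, "r": 0.01},
    "fig1c": {"S": 0.5, "p1": 0.5, "p2": 0.5, "A": 1.0, "B": 0.5, "R": 10, "r": 0.01},
    # majority norm and unpopular minority norm at S=0.8
    "fig3a": {"S": 0.8, "p1": 0.5, "p2": 0.5, "A": 1.0, "B": 0.5, "R": 10, "r": 0.01},
    "fig3b": {"S": 0.8, "p1": 0.25, "p2": 0.9, "A": 1.0, "B": 0.5, "R": 10, "r": 0.01},
    # local cultures at small interaction range
    "fig5a": {"S": 0.5, "p1": 0.5, "p2": 0.5, "A": 1.0, "B": 0.4, "R": 1, "r": 0.01, "T": 100},
    "fig5b": {"S": 0.5, "p1": 0.5, "p2": 0.5, "A": 1.0, "B": 0.4, "R": 2, "r": 0.01, "T": 100},
    # coexistence when B > A
    "fig6": {"S": 0.5, "p1": 0.5, "p2": 0.5, "A": 1.0, "B": 1.2, "R": 10, "r": 0.01},
    # punishment scenarios (B > A so behaviors would coexist unpunished)
    "fig8a_behavior": {
        "S": 0.8, "p1": 0.5, "p2": 0.5, "A": 1.0, "B": 1.2, "R": 2, "r": 0.01,
        "mode": "behavior", "L": 1.5, "k": 3.0,
    },
    "fig8a_preference": {
        "S": 0.8, "p1": 0.5, "p2": 0.5, "A": 1.0, "B": 1.2, "R": 2, "r": 0.01,
        "mode": "preference", "L": 1.5, "k": 3.0,
    },
    "fig8b_preference": {
        "S": 0.6, "p1": 0.5, "p2": 0.5, "A": 1.0, "B": 1.2, "R": 2, "r": 0.01,
        "mode": "preference", "L": 1.5, "k": 3.0,
    },
    "fig9a": {
        "S": 0.8, "p1": 0.5, "p2": 0.5, "A": 1.0, "B": 1.2, "R": 2, "r": 0.01,
        "mode": "behavior", "L": 1.5, "k": 3.0,
    },
    "fig9b": {
        "S": 0.8, "p1": 0.5, "p2": 0.5, "A": 1.0, "B": 1.2, "R": 2, "r": 0.01,
        "mode": "preference", "L": 1.5, "k": 3.0,
    },
    # spontaneous norm emergence through adaptive group pressure
    "fig11": {
        "S": 0.5, "p1": 1.0, "p2": 1.0, "A": 1.0, "B": 1.1, "R": 2, "r": 0.01,
        "mode": "adaptive", "C0": 1.0, "k": 3.0, "T": 4000,
    },
    # persistence: drop C0 after the norm has formed
    "fig12": {
        "S": 0.6, "p1": 1.0, "p2": 1.0, "A": 1.0, "B": 1.1, "R": 2, "r": 0.01,
        "mode": "adaptive", "C0": 1.0, "k": 3.0, "T": 2000,
        "schedule": [{"t0": 1000, "param": "C0", "value": 0.25}],
    },
}
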