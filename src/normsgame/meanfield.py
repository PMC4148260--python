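"""Representative-agent (mean-field) oracle.

In the well-mixed limit an agent displaying its preferred behavior,
surrounded by a share ``s`` of conforming agents, earns ``B + s*A``;
switching to the non-preferred behavior would earn ``(1-s)*A``. A
rational agent therefore abandons its preference when
``B/A < 1 - 2s``. Costly punishment with cost C and fine F effectively
raises the conformity advantage, generalizing the condition to
``B < (1 - 2s) * (A + C + F)``.

Evaluated at ``s = S`` (respectively ``1 - S`` by the 1<->2 relabeling
symmetry) these inequalities predict the three phases of the model
without adaptive pressure: norm of population 1, norm of population 2,
or coexistence of both behaviors. The simulator is validated against
these predictions in the large-interaction-range limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseLabel",
    "NORM1",
    "NORM2",
    "COEXISTENCE",
    "switch_condition",
    "switch_condition_punished",
    "predicted_phase",
    "phase_diagram_analytic",
]

NORM1 = "norm1"
NORM2 = "norm2"
COEXISTENCE = "coexistence"
PHASE_LABELS = (NORM1, NORM2, COEXISTENCE)


@dataclass(frozen=True)
class PhaseLabel:
    """Outcome label: one of norm1, norm2, coexistence."""

    value: str

    def __post_init__(self) -> None:
        if self.value not in PHASE_LABELS:
            raise ValueError(f"unknown phase label {self.value!r}")


def switch_condition(A: float, B: float, s: float) -> bool:
    """True when an agent surrounded by conforming share ``s`` should
    abandon its preferred behavior: B/A < 1 - 2s."""
    if A <= 0:
        raise ValueError("A must be positive")
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must lie in [0, 1]")
    return B / A < 1.0 - 2.0 * s


def switch_condition_punished(
    A: float, B: float, s: float, C: float = 0.0, F: float = 0.0
) -> bool:
    """Switching condition under behavior-based punishment:
    B < (1 - 2s) * (A + C + F). Reduces to :func:`switch_condition`
    at C = F = 0."""
    if A <= 0:
        raise ValueError("A must be positive")
    if C < 0 or F < 0:
        raise ValueError("C and F must be non-negative")
    return B < (1.0 - 2.0 * s) * (A + C + F)


def predicted_phase(
    A: float, B: float, S: float, C: float = 0.0, F: float = 0.0
) -> str:
    """Mean-field phase at population-1 strength S.

    Population 1 abandons its preference (norm of population 2) when the
    switching condition holds at s = S; the mirror case (s = 1 - S, by
    the 1<->2 relabeling symmetry) gives the norm of population 1;
    otherwise the behaviors coexist. Points exactly on a separating line
    are labeled coexistence.
    """
    to_norm2 = switch_condition_punished(A, B, S, C, F)
    to_norm1 = switch_condition_punished(A, B, 1.0 - S, C, F)
    if to_norm1 and to_norm2:
        # possible only for B <= 0; flag rather than guess
        raise ValueError(
            f"both switching conditions hold at A={A}, B={B}, S={S}"
        )
    if to_norm2:
        return NORM2
    if to_norm1:
        return NORM1
    return COEXISTENCE


def phase_diagram_analytic(
    A: float = 1.0,
    ba_values: np.ndarray | None = None,
    s_values: np.ndarray | None = None,
    C: float = 0.0,
    F: float = 0.0,
):
    """Predicted phase on a (B/A, S) mesh; returns a tidy DataFrame."""
    import pandas as pd

    if ba_values is None:
        ba_values = np.linspace(0.0, 1.0, 101)[1:]  # B > 0
    if s_values is None:
        s_values = np.linspace(0.0, 1.0, 101)
    rows = [
        (ba, s, predicted_phase(A, ba * A, s, C, F))
        for ba in ba_values
        for s in s_values
    ]
    return pd.DataFrame(rows, columns=["B_over_A", "S", "label"])
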