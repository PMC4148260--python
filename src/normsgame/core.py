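"""Lattice, parameters, payoff matrix and neighborhood geometry.

The model places ``n_rows * n_cols`` agents on a fully occupied torus.
Each agent has a fixed preference for one of two behaviors (population 1
prefers behavior 1, population 2 prefers behavior 2) and displays a
current behavior that evolves through interaction, imitation and noise.

Payoffs of a pairwise interaction are read off a 2x2-structured matrix:
an agent earns the conformity advantage ``A`` when its displayed behavior
matches the partner's, plus the intrinsic benefit ``B`` when it matches
its own preference (so A+B / B / A / 0 for the four combinations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import NamedTuple

import numpy as np

__all__ = [
    "SimulationParams",
    "GridState",
    "Site",
    "init_grid",
    "payoff_pair",
    "neighborhood",
    "neighborhood_offsets",
]

BEHAVIOR_1 = 1
BEHAVIOR_2 = 2


class Site(NamedTuple):
    """0-based lattice coordinates of one agent."""

    row: int
    col: int


@dataclass(frozen=True)
class SimulationParams:
    """Scalar model parameters and run controls.

    Parameters
    ----------
    A : float
        Advantage of conforming with the interaction partner's behavior
        (payoff units, must be > 0).
    B : float
        Benefit of displaying one's own preferred behavior (payoff
        units, >= 0).
    S : float
        Relative strength of population 1: the share of agents whose
        preference is behavior 1.
    p1, p2 : float
        Initial commitment of each population, i.e. the fraction of its
        members that display their preferred behavior at t = 0.
    R : int
        Interaction range: partners and role models are drawn within
        Chebyshev (default) or Euclidean distance R on the torus.
    r : float
        Per-update probability of a random behavior flip (noise).
    n_rows, n_cols : int
        Lattice dimensions; the grid is a fully occupied torus.
    T : int
        Number of simulation steps; one step updates N/2 focal agents
        and their partners (N = number of agents).
    seed : int
        Default RNG seed for :func:`normsgame.experiments.run_simulation`.
    metric : str
        Neighborhood metric, ``"chebyshev"`` (Moore range, default) or
        ``"euclidean"``.
    noise_scope : str
        ``"pair"`` (default): noise is applied to the two agents updated
        in each round; ``"all"``: every agent is subjected to a flip
        attempt once per step instead.
    """

    A: float = 1.0
    B: float = 0.5
    S: float = 0.5
    p1: float = 0.5
    p2: float = 0.5
    R: int = 10
    r: float = 0.01
    n_rows: int = 50
    n_cols: int = 50
    T: int = 200
    seed: int = 0
    metric: str = "chebyshev"
    noise_scope: str = "pair"

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"A must be positive, got {self.A}")
        if self.B < 0:
            raise ValueError(f"B must be non-negative, got {self.B}")
        for name in ("S", "p1", "p2", "r"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (isinstance(self.R, (int, np.integer)) and self.R >= 1):
            raise ValueError(f"R must be a positive integer, got {self.R}")
        if self.n_rows * self.n_cols < 2:
            raise ValueError("lattice must hold at least 2 agents")
        if 2 * self.R + 1 > min(self.n_rows, self.n_cols):
            raise ValueError(
                f"neighborhood of range R={self.R} wraps onto itself on a "
                f"{self.n_rows}x{self.n_cols} torus (need 2R+1 <= min dim)"
            )
        if self.T < 0:
            raise ValueError("T must be non-negative")
        if self.metric not in ("chebyshev", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.noise_scope not in ("pair", "all"):
            raise ValueError(f"unknown noise_scope {self.noise_scope!r}")

    @property
    def n_agents(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def dims(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def replace(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


@dataclass
class GridState:
    """Mutable per-site state of a running simulation.

    ``preference`` is immutable after initialization; ``behavior`` is the
    currently displayed behavior; ``last_payoff`` is the net payoff from
    the site's most recent interaction (0 before the first one);
    ``cumulative_payoff`` is the running sum of net interaction payoffs
    minus punishment costs paid and fines received.
    """

    preference: np.ndarray
    behavior: np.ndarray
    last_payoff: np.ndarray
    cumulative_payoff: np.ndarray
    t: int = 0

    @property
    def dims(self) -> tuple[int, int]:
        return self.preference.shape

    @property
    def n_agents(self) -> int:
        return self.preference.size

    @property
    def share_b1(self) -> float:
        return float(np.mean(self.behavior == BEHAVIOR_1))

    @property
    def share_b2(self) -> float:
        return float(np.mean(self.behavior == BEHAVIOR_2))

    @property
    def share_preferred(self) -> float:
        return float(np.mean(self.behavior == self.preference))

    def copy(self) -> "GridState":
        return GridState(
            preference=self.preference.copy(),
            behavior=self.behavior.copy(),
            last_payoff=self.last_payoff.copy(),
            cumulative_payoff=self.cumulative_payoff.copy(),
            t=self.t,
        )


def init_grid(params: SimulationParams, rng: np.random.Generator) -> GridState:
    """Initialize a lattice with exact population and commitment counts.

    Exactly ``round(S * N)`` sites receive preference 1, placed by a
    uniform random permutation; within each population, exactly
    ``round(p_i * |pop_i|)`` members start with their preferred behavior,
    again chosen by permutation. Exact-count assignment (rather than
    i.i.d. draws) removes initialization variance from phase-diagram
    estimates.
    """
    n = params.n_agents
    n_pop1 = int(round(params.S * n))
    if n_pop1 in (0, n):
        warnings.warn(
            "one population is empty; per-population statistics will be "
            "undefined",
            stacklevel=2,
        )

    pref = np.full(n, BEHAVIOR_2, dtype=np.int8)
    order = rng.permutation(n)
    pref[order[:n_pop1]] = BEHAVIOR_1

    beh = np.empty(n, dtype=np.int8)
    idx1 = np.flatnonzero(pref == BEHAVIOR_1)
    idx2 = np.flatnonzero(pref == BEHAVIOR_2)
    # population 1: p1 committed to behavior 1, the rest start with 2
    n_c1 = int(round(params.p1 * idx1.size))
    perm1 = rng.permutation(idx1)
    beh[perm1[:n_c1]] = BEHAVIOR_1
    beh[perm1[n_c1:]] = BEHAVIOR_2
    # population 2: p2 committed to behavior 2
    n_c2 = int(round(params.p2 * idx2.size))
    perm2 = rng.permutation(idx2)
    beh[perm2[:n_c2]] = BEHAVIOR_2
    beh[perm2[n_c2:]] = BEHAVIOR_1

    dims = params.dims
    return GridState(
        preference=pref.reshape(dims),
        behavior=beh.reshape(dims),
        last_payoff=np.zeros(dims),
        cumulative_payoff=np.zeros(dims),
        t=0,
    )


def payoff_pair(b: int, c: int, p: int, params: SimulationParams) -> float:
    """Interaction payoff of a focal agent showing ``b`` against a partner
    showing ``c``, given the focal preference ``p``.

    Returns ``A*[b == c] + B*[b == p]``, i.e. the four-cell matrix
    A+B (conform & preferred), B (preferred only), A (conform only), 0.
    """
    if b not in (1, 2) or c not in (1, 2) or p not in (1, 2):
        raise ValueError("behavior/preference codes must be 1 or 2")
    return params.A * (b == c) + params.B * (b == p)


@lru_cache(maxsize=None)
def neighborhood_offsets(R: int, metric: str = "chebyshev") -> np.ndarray:
    """(M, 2) array of (drow, dcol) offsets at distance <= R, self excluded,
    in deterministic row-major order."""
    offs = []
    for dr in range(-R, R + 1):
        for dc in range(-R, R + 1):
            if dr == 0 and dc == 0:
                continue
            if metric == "euclidean" and dr * dr + dc * dc > R * R:
                continue
            offs.append((dr, dc))
    out = np.array(offs, dtype=np.int64)
    out.setflags(write=False)
    return out


def neighborhood(
    site: Site,
    R: int,
    dims: tuple[int, int],
    metric: str = "chebyshev",
) -> list[Site]:
    """All sites within range ``R`` of ``site`` under toroidal wrap-around,
    self excluded, in deterministic row-major offset order.

    With the default Chebyshev metric the neighborhood is the Moore range
    of size ``(2R+1)**2 - 1``; every site on the torus has an identically
    sized neighborhood.
    """
    n_rows, n_cols = dims
    if 2 * R + 1 > min(n_rows, n_cols):
        raise ValueError(
            f"range R={R} wraps onto itself on a {n_rows}x{n_cols} torus"
        )
    offs = neighborhood_offsets(R, metric)
    return [
        Site((site.row + dr) % n_rows, (site.col + dc) % n_cols)
        for dr, dc in offs
    ]
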