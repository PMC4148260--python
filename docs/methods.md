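# Model and methods

## The multi-population norms game

`normsgame` simulates two populations with incompatible, fixed
preferences on a fully occupied two-dimensional torus of `n_rows x
n_cols` agents. A share `S` of agents (population 1) prefers behavior 1;
the rest prefer behavior 2. Each agent displays one of the two behaviors
at any time; preferences never change during a run.

A pairwise interaction between agents displaying `b` and `c` pays the
focal agent

    P_b = A * [b = c] + B * [b = p]

where `p` is its own preference: `A > 0` is the advantage of conforming
with the partner, `B >= 0` the intrinsic benefit of doing what one
prefers (matrix cells A+B / B / A / 0). The interesting regime is the
normative dilemma: a shared behavior pays everyone `A` (plus `B` for
those who prefer it), but whoever abandons their preference forgoes `B`.

### Update rule

Time advances by random sequential updating. One step consists of
`floor(N/2)` rounds (`N = n_rows * n_cols`); each round:

1. **Interaction.** A focal agent is drawn uniformly (with replacement)
   and a partner uniformly within range `R` (Chebyshev/Moore metric by
   default, Euclidean optional; self excluded, toroidal wrap-around, so
   every agent has `(2R+1)^2 - 1` neighbors). Both earn the matrix
   payoff, modified by sanctions (below). Each agent's *last payoff* is
   set to its net result; cumulative payoffs accumulate the same net
   amounts.
2. **Imitation.** Focal and partner each draw a role model uniformly
   among *same-preference* neighbors within `R` (in-group imitation;
   none available means no change). If the model's last interaction paid
   strictly more, the agent adopts the model's current behavior with
   probability `min(1, dP / (A + B))` — the proportional imitation rule.
   The clip matters only under punishment, where payoff gaps can exceed
   `A + B`.
3. **Randomization.** Each of the two updated agents flips to the
   opposite behavior with probability `r` (an `--noise-scope all`
   variant instead applies one flip trial per agent per step; expected
   rates are identical).

Payoff comparisons use last-interaction payoffs as recorded, even when
stale (the model may have interacted long ago, or flipped behavior since
earning them). This is a deliberate feature of the imitation rule, and
it has a visible consequence: noise-flipped agents briefly "advertise"
their new behavior with a payoff earned under the old one, which speeds
the erosion of thin-margin coexistence states (see *Mean-field oracle*).

### Sanctioning

Punishment is unconditional (no cost–benefit calculus). A punisher pays
cost `C`; the punishee receives fine `F = k C` with `k > 1` (default
`k = 3`); the punishment level `L = (k+1) C` summarizes total severity.
Agents never punish when the cost would push their cumulative payoff
negative; the guard is evaluated against the cumulative payoff before
the current round's interaction payoff is credited. Both interaction
partners evaluate sanctioning (focal first; the partner's budget guard
sees a fine it just received). Fines may drive payoffs negative — no
floor exists. Modes:

- **behavior**: sanction a partner displaying a different behavior than
  one's own.
- **preference**: sanction a partner whose display violates one's
  private preference.
- **adaptive**: behavior-triggered, with cost
  `C(N) = C0 (1-N)^4 [2-(1-N)^2]^2`, `N` being the fraction of the
  punisher's range-`R` neighbors (punishee included, self excluded)
  displaying a different behavior than the punisher. `C(0) = C0`,
  `C(1) = 0`, strictly decreasing: local majorities sanction hard.

Every executed sanction is classified: behavior-based (and adaptive)
punishment is *hypocritical* when the punished behavior matches the
punisher's own preference; preference-based punishment is hypocritical
when it matches the punisher's own display. Event logs also record both
parties' displayed behaviors, because under behavior-based rules the
residual deviants themselves sanction conformists; analyses of "who
punishes the deviants" (`deviant_sanction_ratio`) must exclude that
reverse flow, and do so by filtering on the punishee's behavior.

### Mean-field oracle

In the well-mixed limit an agent displaying its preference within a
conforming share `s` earns `B + sA` versus `(1-s)A` after switching, so
it abandons the preference when `B/A < 1 - 2s`; punishment generalizes
this to `B < (1-2s)(A + C + F)`. Evaluated at `s = S` and `s = 1 - S`
(the 1<->2 relabeling), these inequalities predict the three phases
(norm1 / norm2 / coexistence); exact ties are labeled coexistence.

The simulated boundary agrees with the oracle deep inside each region.
Near the line, however, coexistence is only *metastable* at `r > 0`: the
noise-sustained deviant load (of order `r` divided by the imitation
drift margin) plus stale-payoff advertising erode thin majorities, so
the measured flip along `S` sits about 0.05–0.1 above
`S* = (1 - B/A)/2` at a 200-step horizon and drifts further with longer
horizons. The analytic line ignores noise; the discrepancy shrinks with
`r`.

## Parameters, defaults, and scales

| parameter | meaning | default |
|---|---|---|
| `A` | conformity advantage (payoff units) | 1.0 |
| `B` | benefit of preferred behavior | 0.5 |
| `S` | share of population 1 | 0.5 |
| `p1`, `p2` | initial commitment of each population | 0.5 |
| `R` | interaction range (Chebyshev) | 10 |
| `r` | flip probability per update | 0.01 |
| `n_rows x n_cols` | torus size | 50x50 |
| `T` | steps | 200 |
| `C`, `k`, `C0` | punishment cost, fine multiplier, adaptive maximum | 0, 3, 0 |

`A=1, B=0.5, R=10, r=0.01` is the model's baseline; punishment studies
use `B=1.2, R=2` (where behaviors coexist unpunished) and the adaptive
studies `B=1.1, C0=1, k=3, R=2`. The lattice size is a free scale: all
order parameters used here (behavior shares, local conformity, punisher
fractions) are intensive, and the package's standard problem sizes —
40x40 for the R=10 scenarios, 50x50 for local-culture snapshots, 24x24
for adaptive-emergence replicate studies, 30x30 for persistence
schedules — were chosen so that full replicate sets run in minutes on
one core. Adaptive-norm *waiting times* are the one quantity with a
residual size dependence (more sites, more chances for a super-critical
fluctuation), so they are reported only qualitatively.

Initialization realizes `S`, `p1`, `p2` as exact counts via random
permutations rather than i.i.d. draws, removing initialization variance
from phase-diagram estimates. Last payoffs start at 0, the neutral
element of the payoff scale, so never-interacted agents compare as 0 in
imitation.

## Outcome classification

A run is labeled `norm1`/`norm2` when the corresponding behavior is
displayed by at least 80% of agents, `coexistence` when at least 80%
display their own preference, otherwise by the largest of the three
shares (ties to coexistence). The thresholds are configurable; the
phases are visually sharp in practice, so results are insensitive to the
choice within (0.7, 0.9). Classification optionally averages the final
10 steps to damp noise. `local_conformity(R)` — the mean fraction of
range-`R` neighbors sharing an agent's behavior — separates local
cultures (high conformity, mixed global shares) from coexistence.

## Numerical implementation

Production runs use a numba JIT kernel over flat arrays with numba's
deterministic legacy RNG, seeded per run; a readable pure-Python
reference implementation of the identical update lives in
`normsgame.dynamics` and is statistically cross-checked against the
kernel in the tests (the two use different RNG streams, so trajectories
match in distribution, not bitwise). Replicate and sweep seeds derive
from `numpy.random.SeedSequence(base, i, j, rep)`, making every sweep
cell independently reproducible. Optional event recording is capped
(default 2e6 events) to bound memory; per-step sanction counts are
always recorded.

## What the simulations do and do not show

All experiments run on internally generated lattices; there is no
external data. The model abstracts real norm dynamics heavily: two
behaviors, fixed binary preferences, a homogeneous torus, and
unconditional sanctioning. Passing tests therefore demonstrate the
internal self-organization properties of this model class —
path-dependent norm selection, unpopular norms, local cultures,
punishment typology accounting, threshold-driven spontaneous norm birth,
hysteresis under pressure release — not quantitative predictions about
any empirical society.

Known limitations worth keeping in mind:

- Near-boundary phase measurements are horizon-dependent (metastability
  above); boundary-location checks should be read with a tolerance of
  about 0.1 in `S` at `r = 0.01`.
- Domain coarsening in the local-culture regime (`R=1, B/A=0.4`) is
  slow: neighbor conformity is ~0.7 after 100 steps and crosses 0.75
  only around t ≈ 1000. Snapshots of this regime at t = 100 show
  small, ragged domains.
- Adaptive-norm emergence times are stochastic waiting times; only
  their order of magnitude and their divergence (at `r = 0`, `C0 = 0`,
  or large `R`) are meaningful.
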