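"""JIT-compiled simulation kernel.

Implements exactly the update of :mod:`normsgame.dynamics` (interaction,
in-group proportional imitation, noise, sanctioning with the
cumulative-payoff guard) on flat arrays, fast enough for phase-diagram
sweeps and long adaptive-pressure horizons.

The kernel uses numba's deterministic legacy RNG seeded once per run;
it is cross-validated against the pure-Python reference engine in the
test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# mode codes (keep in sync with sanctioning.MODES)
MODE_NONE = 0
MODE_BEHAVIOR = 1
MODE_PREFERENCE = 2
MODE_ADAPTIVE = 3

# schedule parameter codes
SCHED_R = 0  # noise rate r
SCHED_C = 1
SCHED_C0 = 2

# metrics columns
METRIC_COLUMNS = (
    "share_b1",
    "share_preferred",
    "mean_payoff",
    "n_sanctions_sincere",
    "n_sanctions_hypocritical",
    "n_punishers_sincere",
    "n_punishers_hypocritical",
)


@njit(cache=True)
def _adaptive_cost(nonconform_frac, C0):
    u = 1.0 - nonconform_frac
    return C0 * u**4 * (2.0 - u * u) ** 2


@njit(cache=True)
def _nonconforming_fraction(beh, ego, offsets, n_rows, n_cols):
    er = ego // n_cols
    ec = ego % n_cols
    b = beh[ego]
    diff = 0
    m = offsets.shape[0]
    for i in range(m):
        nr = (er + offsets[i, 0]) % n_rows
        nc = (ec + offsets[i, 1]) % n_cols
        if beh[nr * n_cols + nc] != b:
            diff += 1
    return diff / m


@njit(cache=True)
def run_kernel(
    pref,
    beh,
    n_rows,
    n_cols,
    offsets,
    A,
    B,
    r,
    T,
    mode,
    C,
    k,
    C0,
    mutual,
    noise_all,
    sched_t,
    sched_code,
    sched_val,
    stop_threshold,
    seed,
    record_events,
    max_events,
):
    """Advance T steps (or until one behavior reaches stop_threshold).

    Returns (metrics, last_pay, cum_pay, t_final, events_int, events_flt,
    n_events, totals) where metrics has one row per completed step with
    columns METRIC_COLUMNS, events_int rows are (t, punisher, punishee,
    label, punisher_behavior, punishee_behavior) with label 0=sincere
    1=hypocritical, events_flt rows are (cost, fine), and totals is
    (gross payoff sum, cost sum, fine sum) for accounting checks.
    """
    np.random.seed(seed)
    n = n_rows * n_cols
    m = offsets.shape[0]
    last_pay = np.zeros(n)
    cum_pay = np.zeros(n)
    metrics = np.zeros((T, 7))
    cap = max_events if record_events else 1
    events_int = np.zeros((cap, 6), dtype=np.int64)
    events_flt = np.zeros((cap, 2))
    n_events = 0
    punished_sin = np.zeros(n, dtype=np.uint8)
    punished_hyp = np.zeros(n, dtype=np.uint8)
    buf = np.empty(m, dtype=np.int64)
    pair = np.empty(2, dtype=np.int64)
    rounds = n // 2
    total_gross = 0.0
    total_cost = 0.0
    total_fine = 0.0
    t_final = 0

    for t in range(T):
        for si in range(sched_t.shape[0]):
            if sched_t[si] == t:
                if sched_code[si] == SCHED_R:
                    r = sched_val[si]
                elif sched_code[si] == SCHED_C:
                    C = sched_val[si]
                else:
                    C0 = sched_val[si]
        ev_sin = 0
        ev_hyp = 0
        for i in range(n):
            punished_sin[i] = 0
            punished_hyp[i] = 0

        for _ in range(rounds):
            f = np.random.randint(n)
            fr = f // n_cols
            fc = f % n_cols
            o = offsets[np.random.randint(m)]
            g = ((fr + o[0]) % n_rows) * n_cols + (fc + o[1]) % n_cols

            bf = beh[f]
            bg = beh[g]
            pb = A * (bf == bg) + B * (bf == pref[f])
            pc = A * (bf == bg) + B * (bg == pref[g])
            total_gross += pb + pc
            df = 0.0  # punishment flows hitting the focal agent
            dg = 0.0

            if mode != MODE_NONE:
                n_dir = 2 if mutual else 1
                for d in range(n_dir):
                    if d == 0:
                        ego, alter = f, g
                    else:
                        ego, alter = g, f
                    b_ego = beh[ego]
                    b_alt = beh[alter]
                    if mode == MODE_PREFERENCE:
                        trigger = b_alt != pref[ego]
                        cost = C
                    else:
                        trigger = b_alt != b_ego
                        if mode == MODE_ADAPTIVE:
                            cost = _adaptive_cost(
                                _nonconforming_fraction(
                                    beh, ego, offsets, n_rows, n_cols
                                ),
                                C0,
                            )
                        else:
                            cost = C
                    if trigger:
                        # budget guard on cumulative payoff before this
                        # round's interaction payoff, but after any fine
                        # already received in this round
                        d_ego = df if ego == f else dg
                        if cum_pay[ego] + d_ego - cost < 0:
                            trigger = False
                    if trigger:
                        fine = k * cost
                        if ego == f:
                            df -= cost
                            dg -= fine
                        else:
                            dg -= cost
                            df -= fine
                        total_cost += cost
                        total_fine += fine
                        if mode == MODE_PREFERENCE:
                            hyp = b_alt == b_ego
                        else:
                            hyp = b_alt == pref[ego]
                        if hyp:
                            ev_hyp += 1
                            punished_hyp[ego] = 1
                        else:
                            ev_sin += 1
                            punished_sin[ego] = 1
                        if record_events and n_events < cap:
                            events_int[n_events, 0] = t + 1
                            events_int[n_events, 1] = ego
                            events_int[n_events, 2] = alter
                            events_int[n_events, 3] = 1 if hyp else 0
                            events_int[n_events, 4] = b_ego
                            events_int[n_events, 5] = b_alt
                            events_flt[n_events, 0] = cost
                            events_flt[n_events, 1] = fine
                            n_events += 1

            last_pay[f] = pb + df
            last_pay[g] = pc + dg
            cum_pay[f] += pb + df
            cum_pay[g] += pc + dg

            # imitation: focal then partner, each with its own role model
            pair[0] = f
            pair[1] = g
            for a in range(2):
                ag = pair[a]
                ar = ag // n_cols
                ac = ag % n_cols
                p_ag = pref[ag]
                cnt = 0
                for i in range(m):
                    nr = (ar + offsets[i, 0]) % n_rows
                    nc = (ac + offsets[i, 1]) % n_cols
                    nb = nr * n_cols + nc
                    if pref[nb] == p_ag:
                        buf[cnt] = nb
                        cnt += 1
                if cnt > 0:
                    model = buf[np.random.randint(cnt)]
                    diff = last_pay[model] - last_pay[ag]
                    if diff > 0:
                        prob = diff / (A + B)
                        if prob > 1.0:
                            prob = 1.0
                        if np.random.random() < prob:
                            beh[ag] = beh[model]

            if not noise_all:
                for a in range(2):
                    if np.random.random() < r:
                        beh[pair[a]] = 3 - beh[pair[a]]

        if noise_all:
            for i in range(n):
                if np.random.random() < r:
                    beh[i] = 3 - beh[i]

        n_b1 = 0
        n_prefd = 0
        pay = 0.0
        for i in range(n):
            if beh[i] == 1:
                n_b1 += 1
            if beh[i] == pref[i]:
                n_prefd += 1
            pay += last_pay[i]
        share_b1 = n_b1 / n
        metrics[t, 0] = share_b1
        metrics[t, 1] = n_prefd / n
        metrics[t, 2] = pay / n
        metrics[t, 3] = ev_sin
        metrics[t, 4] = ev_hyp
        metrics[t, 5] = punished_sin.sum()
        metrics[t, 6] = punished_hyp.sum()
        t_final = t + 1
        if stop_threshold > 0.0 and (
            share_b1 >= stop_threshold or 1.0 - share_b1 >= stop_threshold
        ):
            break

    totals = np.array([total_gross, total_cost, total_fine])
    return (
        metrics[:t_final],
        last_pay,
        cum_pay,
        t_final,
        events_int[:n_events],
        events_flt[:n_events],
        n_events,
        totals,
    )
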