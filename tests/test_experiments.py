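import numpy as np
import pandas as pd
import pytest

from normsgame import (
    COEXISTENCE,
    NORM1,
    NORM2,
    PunishmentConfig,
    Schedule,
    ScheduleEntry,
    SimulationParams,
    classify_outcome,
    classify_shares,
    init_grid,
    local_conformity,
    phase_sweep,
    punisher_proportions,
    run_simulation,
)


def make_state(params, seed=0):
    return init_grid(params, np.random.default_rng(seed))


class TestClassifyOutcome:
    def test_uniform_behavior_is_norm(self):
        p = SimulationParams(S=0.5, n_rows=10, n_cols=10, R=2)
        state = make_state(p)
        state.behavior[:, :] = 1
        assert classify_outcome(state) == NORM1

    def test_full_commitment_is_coexistence(self):
        p = SimulationParams(S=0.5, p1=1.0, p2=1.0, n_rows=10, n_cols=10, R=2)
        state = make_state(p)
        assert classify_outcome(state) == COEXISTENCE

    def test_threshold_classification(self):
        assert classify_shares(0.95, 0.05, 0.5) == NORM1
        assert classify_shares(0.05, 0.95, 0.5) == NORM2
        assert classify_shares(0.6, 0.4, 0.85) == COEXISTENCE
        # below all thresholds: largest quantity wins, ties to coexistence
        assert classify_shares(0.7, 0.3, 0.6) == NORM1
        assert classify_shares(0.7, 0.3, 0.7) == COEXISTENCE

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            classify_shares(0.5, 0.5, 0.5, norm_threshold=0.4)


class TestLocalConformity:
    def test_uniform_grid_is_one(self):
        p = SimulationParams(S=0.5, n_rows=8, n_cols=8, R=1)
        state = make_state(p)
        state.behavior[:, :] = 2
        assert local_conformity(state, 1) == pytest.approx(1.0)

    def test_checkerboard_half(self):
        """On a behavior checkerboard each agent agrees with exactly the
        4 diagonal members of its 8-cell Moore neighborhood."""
        p = SimulationParams(S=0.5, n_rows=8, n_cols=8, R=1)
        state = make_state(p)
        i, j = np.indices((8, 8))
        state.behavior[:, :] = 1 + ((i + j) % 2)
        assert local_conformity(state, 1) == pytest.approx(0.5)

    def test_random_grid_matches_share_squares(self):
        """For i.i.d. behaviors the expected conformity is s1^2 + s2^2
        (evaluated here at s = 1/2)."""
        p = SimulationParams(S=0.5, n_rows=50, n_cols=50, R=1)
        state = make_state(p)
        rng = np.random.default_rng(0)
        state.behavior[:, :] = rng.integers(1, 3, size=(50, 50))
        assert local_conformity(state, 1) == pytest.approx(0.5, abs=0.02)


class TestSchedule:
    def test_only_punishment_params_and_noise_schedulable(self):
        Schedule((ScheduleEntry(10, "C0", 0.25),))
        Schedule((ScheduleEntry(5, "r", 0.0), ScheduleEntry(9, "C", 0.1)))
        with pytest.raises(ValueError):
            ScheduleEntry(10, "A", 2.0)

    def test_times_strictly_increasing(self):
        with pytest.raises(ValueError):
            Schedule((ScheduleEntry(10, "C0", 1.0), ScheduleEntry(10, "C0", 0.5)))

    def test_schedule_applied_mid_run(self):
        """Scheduling r=1 turns the dynamics into coin flipping, visible
        in the behavior shares after t0."""
        p = SimulationParams(
            S=1.0, p1=1.0, r=0.0, n_rows=10, n_cols=10, R=2, T=30
        )
        sched = Schedule((ScheduleEntry(10, "r", 0.5),))
        res = run_simulation(p, schedule=sched, seed=0)
        ts = res.timeseries
        assert (ts[ts.t <= 10]["share_preferred"] == 1.0).all()
        assert ts[ts.t > 20]["share_preferred"].mean() < 0.8


class TestRunSimulation:
    def test_deterministic_given_seed(self):
        p = SimulationParams(S=0.5, n_rows=12, n_cols=12, R=2, T=10)
        a = run_simulation(p, seed=42)
        b = run_simulation(p, seed=42)
        pd.testing.assert_frame_equal(a.timeseries, b.timeseries)
        assert np.array_equal(a.state.behavior, b.state.behavior)

    def test_different_seeds_differ(self):
        p = SimulationParams(S=0.5, n_rows=12, n_cols=12, R=2, T=10)
        a = run_simulation(p, seed=1)
        b = run_simulation(p, seed=2)
        assert not np.array_equal(a.state.behavior, b.state.behavior)

    def test_stop_threshold_halts_early(self):
        p = SimulationParams(S=1.0, p1=1.0, r=0.0, n_rows=10, n_cols=10, R=2, T=50)
        res = run_simulation(p, seed=0, stop_threshold=0.9)
        assert res.stopped_early and res.t_final == 1

    def test_population_label_symmetry(self):
        """Swapping population labels, (p1,S) <-> (p2,1-S), yields the
        mirrored trajectory distribution."""
        kw = dict(n_rows=20, n_cols=20, R=3, T=40)
        a = [
            run_simulation(
                SimulationParams(S=0.3, p1=0.8, p2=0.4, **kw), seed=s
            ).tail_means(10)["share_b1"]
            for s in range(6)
        ]
        b = [
            run_simulation(
                SimulationParams(S=0.7, p1=0.4, p2=0.8, **kw), seed=100 + s
            ).tail_means(10)["share_b2"]
            for s in range(6)
        ]
        assert np.mean(a) == pytest.approx(np.mean(b), abs=0.1)

    def test_engines_agree_statistically(self):
        """JIT and reference engines produce the same coexistence level
        in the high-benefit regime."""
        p = SimulationParams(
            A=1, B=1.2, S=0.5, p1=0.5, p2=0.5, R=2, r=0.01,
            n_rows=16, n_cols=16, T=30,
        )
        a = np.mean(
            [run_simulation(p, seed=s, engine="numba").tail_means(5)["share_preferred"]
             for s in range(4)]
        )
        b = np.mean(
            [run_simulation(p, seed=s, engine="python").tail_means(5)["share_preferred"]
             for s in range(4)]
        )
        assert a == pytest.approx(b, abs=0.06)
        assert a > 0.85  # coexistence: most agents show their preference


class TestNoiseEffect:
    def test_more_noise_means_more_erroneous_deviants(self):
        """In the coexistence regime (B > A) the time-averaged share of
        agents displaying their preference decreases with the flip rate."""
        def mean_pref(r):
            p = SimulationParams(
                A=1, B=1.2, S=0.5, p1=1.0, p2=1.0, R=2, r=r,
                n_rows=20, n_cols=20, T=40,
            )
            return np.mean([
                run_simulation(p, seed=s).tail_means(20)["share_preferred"]
                for s in range(3)
            ])

        m1, m2, m3 = mean_pref(0.005), mean_pref(0.03), mean_pref(0.1)
        assert m1 > m2 > m3


class TestPhaseSweep:
    def test_reduces_to_replicated_run(self):
        p = SimulationParams(p1=1.0, r=0.0, n_rows=16, n_cols=16, R=3, T=10)
        d = phase_sweep(p, ("S", [1.0]), ("B", [0.5]), replicates=3, seed=0)
        assert d.counts.sum() == 3
        assert d.majority_label[0, 0] == NORM1

    def test_reproducible_from_seed(self):
        p = SimulationParams(n_rows=12, n_cols=12, R=2, T=15)
        d1 = phase_sweep(p, ("S", [0.3, 0.7]), ("B", [0.4]), replicates=2, seed=9)
        d2 = phase_sweep(p, ("S", [0.3, 0.7]), ("B", [0.4]), replicates=2, seed=9)
        assert np.array_equal(d1.counts, d2.counts)

    def test_empty_axis_rejected(self):
        p = SimulationParams(n_rows=12, n_cols=12, R=2)
        with pytest.raises(ValueError):
            phase_sweep(p, ("S", []), ("B", [0.5]), replicates=1)

    def test_punishment_level_axis(self):
        p = SimulationParams(n_rows=12, n_cols=12, R=2, T=5)
        d = phase_sweep(
            p, ("L", [0.0, 1.0]), ("S", [0.5]), replicates=1, seed=0,
            punish=PunishmentConfig(mode="behavior", k=3.0),
        )
        assert d.counts.sum() == 2


class TestPunisherProportions:
    def test_empty_log_gives_zero_fractions(self):
        ev = pd.DataFrame(
            columns=[
                "t", "punisher_row", "punisher_col", "punishee_row",
                "punishee_col", "mode", "label", "cost", "fine",
                "punisher_behavior", "punishee_behavior",
            ]
        )
        out = punisher_proportions(ev, window=10, n_agents=100, t_max=20)
        assert (out["frac_events_sincere"] == 0).all()
        assert (out["frac_agents_hypocritical"] == 0).all()

    def test_counts_distinct_agents_once_per_window(self):
        rows = [
            (1, 0, 0, 1, 1, "behavior", "sincere", 0.5, 1.5, 1, 2),
            (2, 0, 0, 2, 2, "behavior", "sincere", 0.5, 1.5, 1, 2),
            (3, 1, 0, 2, 2, "behavior", "hypocritical", 0.5, 1.5, 1, 2),
        ]
        ev = pd.DataFrame(
            rows,
            columns=[
                "t", "punisher_row", "punisher_col", "punishee_row",
                "punishee_col", "mode", "label", "cost", "fine",
                "punisher_behavior", "punishee_behavior",
            ],
        )
        out = punisher_proportions(ev, window=5, n_agents=10, t_max=5)
        row = out.iloc[0]
        assert row.n_events == 3
        assert row.frac_events_sincere == pytest.approx(2 / 3)
        # agent (0,0) punished twice but counts once
        assert row.frac_agents_sincere == pytest.approx(0.1)
        assert row.frac_agents_hypocritical == pytest.approx(0.1)
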