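"""Sample-based planners, SMDP oracles, and decision accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrlplan.planners import (
    ActionSet,
    Planner,
    TrialRecord,
    greedy_rollout,
    min_decision_count,
    moving_average,
    plan_trial,
    run_planning,
    smdp_value_iteration,
)


def chain_options(chain7):
    """Two options aggregating a 7-action chain: 4 actions then 3 actions."""
    from hrlplan.envs import RIGHT
    from hrlplan.options import Option

    a = Option(
        "first_leg",
        initiation_set=frozenset({(0, 0)}),
        policy={(0, c): RIGHT for c in range(4)},
        subgoal=(0, 4),
        termination={(0, c): 0.0 for c in range(1, 4)},
    )
    b = Option(
        "second_leg",
        initiation_set=frozenset({(0, 4)}),
        policy={(0, c): RIGHT for c in range(4, 7)},
        subgoal=(0, 7),
        termination={(0, c): 0.0 for c in range(5, 7)},
    )
    return [a, b]


class TestPlanTrial:
    def test_corridor_flat_converged(self, corridor, rng):
        planner = Planner(corridor, ActionSet.flat())
        for _ in range(30):
            plan_trial(planner, rng=rng)
        planner.epsilon = 0.0
        rec = plan_trial(planner, rng=rng)
        assert rec.primitive_steps == 5 and rec.decisions == 5 and rec.completed

    def test_chain_saltatory_two_decisions(self, chain7, rng):
        """Aggregating a 7-action chain into two options: goal in 2 choices."""
        aset = ActionSet.saltatory(chain7, chain_options(chain7))
        planner = Planner(chain7, aset)
        for _ in range(60):
            plan_trial(planner, rng=rng)
        planner.epsilon = 0.0
        best = min(
            plan_trial(planner, rng=rng).decisions for _ in range(20)
        )
        assert best == 2

    def test_start_equals_goal_rejected(self, corridor, rng):
        planner = Planner(corridor, ActionSet.flat())
        with pytest.raises(ValueError):
            plan_trial(planner, start=corridor.goal, goal=corridor.goal, rng=rng)

    def test_decisions_never_exceed_steps(self, rooms, rooms_action_sets, rng):
        planner = Planner(rooms, rooms_action_sets["hierarchical"])
        for _ in range(15):
            rec = plan_trial(planner, rng=rng)
            assert rec.decisions <= rec.primitive_steps

    def test_trial_record_invariant(self):
        with pytest.raises(ValueError):
            TrialRecord(0, primitive_steps=3, decisions=5, completed=True)


class TestConvergence:
    def test_rooms_flat_greedy_reaches_bfs_minimum(self, rooms):
        rng = np.random.default_rng(0)
        planner = Planner(rooms, ActionSet.flat())
        for _ in range(400):
            plan_trial(planner, rng=rng)
        steps, decisions, ok = greedy_rollout(planner, rooms.start, rng)
        assert ok and steps == 20 == decisions

    def test_rooms_hierarchical_below_flat_early(self, rooms, rooms_action_sets):
        """Mean trial-10 step count: options accelerate early planning."""
        n_runs, trial = 20, 10
        means = {}
        for name in ("flat", "hierarchical"):
            tot = 0
            for seed in range(n_runs):
                rng = np.random.default_rng(seed)
                p = Planner(rooms, rooms_action_sets[name])
                for t in range(trial + 1):
                    rec = plan_trial(p, rng=rng)
                tot += rec.primitive_steps
            means[name] = tot / n_runs
        assert means["hierarchical"] < means["flat"]


class TestRunPlanning:
    def test_equal_seeds_identical_rows(self, corridor):
        df = run_planning(corridor, ActionSet.flat(), 10, 2, seeds=[3, 3])
        a = df[df.run == 0].drop(columns="run").reset_index(drop=True)
        b = df[df.run == 1].drop(columns="run").reset_index(drop=True)
        assert a.equals(b)

    def test_seed_count_validated(self, corridor):
        with pytest.raises(ValueError):
            run_planning(corridor, ActionSet.flat(), 5, 2, seeds=[1])

    def test_schema(self, corridor):
        df = run_planning(corridor, ActionSet.flat(), 5, 1, seeds=[0])
        assert list(df.columns) == [
            "run", "trial", "agent", "primitive_steps", "decisions", "completed",
        ]
        assert (df.agent == "flat").all()


class TestSmdpValueIteration:
    def test_corridor_undiscounted_path_sum(self, corridor):
        V = smdp_value_iteration(corridor, ActionSet.flat(), gamma=1.0)
        assert V[corridor.start] == pytest.approx(-5.0)

    def test_options_preserve_flat_optimum(self, rooms, rooms_action_sets):
        Vf = smdp_value_iteration(rooms, rooms_action_sets["flat"])
        Vo = smdp_value_iteration(rooms, rooms_action_sets["saltatory"])
        dmax = max(abs(Vf[s] - Vo[s]) for s in rooms.free_states)
        assert dmax < 1e-8

    def test_options_only_reachability(self, chain7):
        """Without primitives, V is defined only where options chain to goal."""
        opts = chain_options(chain7)
        aset = ActionSet(primitives=(), options=tuple(opts))
        V = smdp_value_iteration(chain7, aset)
        finite = {s for s, v in V.items() if np.isfinite(v)}
        assert finite == {(0, 0), (0, 4), (0, 7)}

    def test_greedy_attains_oracle_value(self, two_rooms):
        """Converged sample-based planner attains the value-iteration optimum."""
        from hrlplan.envs import step

        V = smdp_value_iteration(two_rooms, ActionSet.flat())
        rng = np.random.default_rng(1)
        planner = Planner(two_rooms, ActionSet.flat())
        for _ in range(200):
            plan_trial(planner, rng=rng)
        s, ret, t = two_rooms.start, 0.0, 0
        while s != two_rooms.goal:
            col = planner._greedy(two_rooms.state_index[s], rng)
            s, r, _, done = planner._transition(col, s, rng)
            ret += two_rooms.discount**t * r
            t += 1
            if done:
                break
        assert ret == pytest.approx(V[two_rooms.start], abs=1e-9)


class TestDecisionAccounting:
    def test_chain_min_decisions(self, chain7):
        opts = chain_options(chain7)
        assert min_decision_count(chain7, ActionSet.flat()) == 7
        assert min_decision_count(chain7, ActionSet.saltatory(chain7, opts)) == 2

    def test_rooms_min_decisions(self, rooms, rooms_action_sets):
        assert min_decision_count(rooms, rooms_action_sets["flat"]) == 20
        assert min_decision_count(rooms, rooms_action_sets["saltatory"]) == 8

    def test_monotone_improvement_in_blocks(self, rooms):
        """Across 10-trial blocks, mean steps never significantly increase."""
        import scipy.stats as sst

        n_runs = 15
        blocks = np.zeros((n_runs, 5))
        for seed in range(n_runs):
            rng = np.random.default_rng(100 + seed)
            p = Planner(rooms, ActionSet.flat())
            steps = [plan_trial(p, rng=rng).primitive_steps for _ in range(50)]
            blocks[seed] = [np.mean(steps[i : i + 10]) for i in range(0, 50, 10)]
        for b in range(4):
            worse = int((blocks[:, b + 1] > blocks[:, b]).sum())
            # one-sided binomial: significant increase would refute learning
            p_inc = sst.binomtest(worse, n_runs, 0.5, alternative="greater").pvalue
            assert p_inc > 0.01


class TestMovingAverage:
    def test_basic(self):
        assert list(moving_average([1, 2, 3, 4], 2)) == [1.5, 2.5, 3.5]

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_window_one_is_identity(self, xs):
        assert np.allclose(moving_average(xs, 1), xs)

    @given(st.integers(1, 20), st.integers(1, 20), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_constant_series_invariant(self, n, w, c):
        if w > n:
            with pytest.raises(ValueError):
                moving_average([c] * n, w)
        else:
            out = moving_average([c] * n, w)
            assert len(out) == n - w + 1
            assert np.allclose(out, c)
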