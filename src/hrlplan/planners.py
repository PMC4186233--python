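"""Sample-based model-based planners: flat, hierarchical, saltatory.

Planning is modelled as a series of internal simulation trials.  Each
trial starts at the start cell and samples an epsilon-greedy trajectory
against the agent's internal model until the goal is reached, applying
tabular temporal-difference updates along the way (SMDP updates with a
gamma**k backup for temporally extended transitions).

Three agents differ only in their action set and transition machinery:

* **flat** — primitive actions only; every simulated step is a decision.
* **hierarchical** (non-saltatory) — primitives plus options, but a flat
  transition model: launching an option is one decision, after which its
  policy is executed step-by-step through the primitive model.
* **saltatory** — primitives plus options *with option models*: a launch
  is one decision and the trajectory leaps straight to the option's
  predicted termination state, skipping the intermediate steps.

Exact SMDP value iteration over the same action sets provides the
planning oracles (minimum step and decision counts).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .envs import ACTIONS, Cell, GridWorld, step
from .options import Option, OptionModel, compute_option_model_exact

__all__ = [
    "ActionSet",
    "Planner",
    "TrialRecord",
    "plan_trial",
    "greedy_rollout",
    "run_planning",
    "smdp_value_iteration",
    "min_decision_count",
    "moving_average",
]


@dataclass
class ActionSet:
    """Primitive actions plus (optionally) options and their models."""

    primitives: tuple[int, ...] = ACTIONS
    options: tuple[Option, ...] = ()
    option_models: Mapping[str, OptionModel] | None = None
    use_option_models: bool = False

    def __post_init__(self) -> None:
        self.primitives = tuple(self.primitives)
        self.options = tuple(self.options)
        if self.use_option_models:
            models = self.option_models or {}
            missing = [o.id for o in self.options if o.id not in models]
            if missing:
                raise ValueError(f"options without models: {missing}")

    @classmethod
    def flat(cls) -> "ActionSet":
        return cls()

    @classmethod
    def hierarchical(cls, options: Iterable[Option]) -> "ActionSet":
        return cls(options=tuple(options))

    @classmethod
    def saltatory(
        cls, world: GridWorld, options: Iterable[Option]
    ) -> "ActionSet":
        opts = tuple(options)
        models = {o.id: compute_option_model_exact(world, o) for o in opts}
        return cls(options=opts, option_models=models, use_option_models=True)

    @property
    def agent_name(self) -> str:
        if not self.options:
            return "flat"
        return "saltatory" if self.use_option_models else "hierarchical"

    @property
    def n_actions(self) -> int:
        return len(self.primitives) + len(self.options)


@dataclass
class TrialRecord:
    """Outcome of one internal planning trial."""

    trial_index: int
    primitive_steps: int
    decisions: int
    completed: bool
    would_have_taken: int | None = None
    rollout_censored: bool = False

    def __post_init__(self) -> None:
        if self.decisions > self.primitive_steps:
            raise ValueError("decisions cannot exceed primitive steps")


class Planner:
    """Tabular epsilon-greedy SMDP Q-learner planning against a model.

    The Q-table is a dense array over (state index, action column) where
    columns ``0..3`` are primitives and subsequent columns are options in
    action-set order.  Option columns are masked (-inf) outside their
    initiation sets.  Q is initialised at 0, which is optimistic under
    negative step rewards and drives systematic exploration.
    """

    def __init__(
        self,
        world: GridWorld,
        action_set: ActionSet,
        alpha: float = 1.0,
        epsilon: float = 0.1,
        gamma: float | None = None,
        intra_updates: bool = True,
    ):
        if not action_set.primitives:
            raise ValueError("planner requires a non-empty primitive action set")
        if not (0.0 < alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if not (0.0 <= epsilon <= 1.0):
            raise ValueError("epsilon must be in [0, 1]")
        self.world = world
        self.action_set = action_set
        self.alpha = alpha
        self.epsilon = epsilon
        self.gamma = world.discount if gamma is None else gamma
        self.intra_updates = intra_updates
        n = world.n_states
        self.n_prim = len(action_set.primitives)
        self.q = np.zeros((n, action_set.n_actions))
        self.visit_counts = np.zeros((n, action_set.n_actions), dtype=np.int64)
        self._mask = np.ones((n, action_set.n_actions), dtype=bool)
        for j, opt in enumerate(action_set.options):
            col = self.n_prim + j
            self._mask[:, col] = False
            for cell in opt.initiation_set:
                self._mask[world.state_index[cell], col] = True
        self.q[~self._mask] = -np.inf
        self._trials_run = 0

    # -- views -------------------------------------------------------------

    @property
    def q_table(self) -> dict[tuple[Cell, object], float]:
        """Mapping view (cell, action-or-option-id) -> Q value."""
        out = {}
        names = list(self.action_set.primitives) + [
            o.id for o in self.action_set.options
        ]
        for i, s in enumerate(self.world.free_states):
            for j, a in enumerate(names):
                if self._mask[i, j]:
                    out[(s, a)] = float(self.q[i, j])
        return out

    # -- action selection --------------------------------------------------

    def _greedy(self, i: int, rng: np.random.Generator) -> int:
        row = self.q[i]
        best = row.max()
        ties = np.flatnonzero(row >= best - 1e-12)
        if len(ties) == 1:
            return int(ties[0])
        return int(ties[rng.integers(len(ties))])

    def select(self, i: int, rng: np.random.Generator) -> int:
        if self.epsilon > 0 and rng.random() < self.epsilon:
            avail = np.flatnonzero(self._mask[i])
            return int(avail[rng.integers(len(avail))])
        return self._greedy(i, rng)

    def _max_q(self, i: int) -> float:
        return float(self.q[i].max())

    # -- transitions -------------------------------------------------------

    def _transition(
        self, col: int, state: Cell, rng: np.random.Generator, learn: bool = False
    ) -> tuple[Cell, float, int, bool]:
        """Apply action column ``col`` at ``state`` in the internal model.

        Returns (next_state, cumulative discounted reward, duration k,
        reached_goal).  With ``learn=True`` a non-saltatory agent also
        applies primitive-level TD updates for every primitive step it
        simulates while executing an option: every outcome the agent
        projects with its flat model improves its plan.  The saltatory
        agent leaps via the option model and never sees those steps.
        """
        world = self.world
        if col < self.n_prim:
            a = self.action_set.primitives[col]
            nxt, r, done = step(world, state, a, rng)
            return nxt, r, 1, done
        opt = self.action_set.options[col - self.n_prim]
        if self.action_set.use_option_models:
            model = self.action_set.option_models[opt.id]
            nxt, k = model.sample(state, rng)
            r = model.expected_reward[state]
            return nxt, r, k, nxt == world.goal
        # non-saltatory: execute the option policy through the primitive model
        s, k, r = state, 0, 0.0
        while True:
            a = opt.policy[s]
            nxt, reward, done = step(world, s, a, rng)
            if learn and self.intra_updates:
                self.update(
                    world.state_index[s], a, reward, 1, world.state_index[nxt], done
                )
            r += self.gamma**k * reward
            k += 1
            s = nxt
            if done:
                return s, r, k, True
            if s == opt.subgoal or opt.beta(s) >= 1.0:
                return s, r, k, False
            if k > 10 * world.n_states:
                raise RuntimeError(f"option {opt.id!r} failed to terminate")

    def update(self, i: int, col: int, r: float, k: int, j: int, done: bool) -> None:
        target = r if done else r + self.gamma**k * self._max_q(j)
        self.q[i, col] += self.alpha * (target - self.q[i, col])
        self.visit_counts[i, col] += 1


def plan_trial(
    planner: Planner,
    world: GridWorld | None = None,
    action_set: ActionSet | None = None,
    start: Cell | None = None,
    goal: Cell | None = None,
    rng: np.random.Generator | None = None,
    step_cap: int | None = None,
) -> TrialRecord:
    """Simulate one planning trial from start to goal with learning.

    The trajectory is sampled epsilon-greedily against the internal
    model; Q-updates are applied after every decision (gamma**k SMDP
    backup for option transitions).  Trials exceeding ``step_cap``
    primitive steps (default ``10 * |S|``) are cut off with
    ``completed=False``.
    """
    world = world or planner.world
    start = start or world.start
    goal = goal or world.goal
    if start == goal:
        raise ValueError("start must differ from goal")
    rng = rng if rng is not None else np.random.default_rng()
    cap = step_cap or 10 * world.n_states
    s = start
    steps = decisions = 0
    while s != goal and steps < cap:
        i = world.state_index[s]
        col = planner.select(i, rng)
        nxt, r, k, done = planner._transition(col, s, rng, learn=True)
        decisions += 1
        steps += k
        planner.update(i, col, r, k, world.state_index[nxt], done)
        s = nxt
        if done:
            break
    completed = s == goal
    planner._trials_run += 1
    return TrialRecord(
        trial_index=planner._trials_run - 1,
        primitive_steps=steps,
        decisions=decisions,
        completed=completed,
        would_have_taken=steps if completed else None,
    )


def greedy_rollout(
    planner: Planner,
    start: Cell,
    rng: np.random.Generator,
    step_cap: int | None = None,
) -> tuple[int, int, bool]:
    """Roll out the current greedy policy (epsilon = 0, no learning).

    Returns (primitive_steps, decisions, reached_goal).  Greedy ties are
    broken uniformly at random; the rollout is capped at ``step_cap``
    primitive steps (default ``10 * |S|``).
    """
    world = planner.world
    cap = step_cap or 10 * world.n_states
    s = start
    steps = decisions = 0
    while s != world.goal and steps < cap:
        i = world.state_index[s]
        col = planner._greedy(i, rng)
        s, _, k, done = planner._transition(col, s, rng)
        decisions += 1
        steps += k
        if done:
            break
    return steps, decisions, s == world.goal


def run_planning(
    world: GridWorld,
    action_set: ActionSet,
    n_trials: int,
    n_runs: int,
    seeds: Sequence[int],
    alpha: float = 1.0,
    epsilon: float = 0.1,
    step_cap: int | None = None,
) -> pd.DataFrame:
    """Repeat the full planning process over independent seeded runs.

    Returns a tidy frame with one row per (run, trial): columns ``run``,
    ``trial``, ``agent``, ``primitive_steps``, ``decisions``,
    ``completed``.  Each run uses a fresh planner and a generator seeded
    from its own entry of ``seeds``, so results are reproducible and
    runs with equal seeds are identical.
    """
    if len(seeds) != n_runs:
        raise ValueError("need exactly one seed per run")
    rows = []
    for run, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        planner = Planner(world, action_set, alpha=alpha, epsilon=epsilon)
        for t in range(n_trials):
            rec = plan_trial(planner, rng=rng, step_cap=step_cap)
            rows.append(
                {
                    "run": run,
                    "trial": t,
                    "agent": action_set.agent_name,
                    "primitive_steps": rec.primitive_steps,
                    "decisions": rec.decisions,
                    "completed": rec.completed,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact oracles


def smdp_value_iteration(
    world: GridWorld,
    action_set: ActionSet | None = None,
    gamma: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> dict[Cell, float]:
    """Exact SMDP value iteration over primitives and/or option models.

    Bellman backups take the max over primitive one-step backups and, for
    any options present, SMDP backups ``E[R] + sum_k gamma**k P(s',k|s) V(s')``
    using exact option models.  States from which no action chains to the
    goal keep value -inf.  The goal is absorbing with value 0.
    """
    action_set = action_set or ActionSet.flat()
    gamma = world.discount if gamma is None else gamma
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    models = dict(action_set.option_models or {})
    for o in action_set.options:
        if o.id not in models:
            models[o.id] = compute_option_model_exact(world, o)
    V = {s: -np.inf for s in world.free_states}
    V[world.goal] = 0.0
    for it in range(max_iter):
        delta = 0.0
        for s in world.free_states:
            if s == world.goal:
                continue
            best = -np.inf
            if action_set.primitives:
                idx = world.state_index[s]
                if world.move_success >= 1.0:
                    for a in action_set.primitives:
                        t = world.free_states[world.next_state_index(idx, a)]
                        r = world.step_reward + (
                            world.goal_reward if t == world.goal else 0.0
                        )
                        v = r + (0.0 if t == world.goal else gamma * V[t])
                        if v > best:
                            best = v
                else:
                    p_ok, p_slip = world.move_success, (1 - world.move_success) / 3.0
                    for a in action_set.primitives:
                        v = 0.0
                        for b in ACTIONS:
                            p = p_ok if b == a else p_slip
                            t = world._move(s, b)
                            r = world.step_reward + (
                                world.goal_reward if t == world.goal else 0.0
                            )
                            v += p * (r + (0.0 if t == world.goal else gamma * V[t]))
                        if v > best:
                            best = v
            for opt in action_set.options:
                if s not in opt.initiation_set:
                    continue
                m = models[opt.id]
                v = m.expected_reward[s]
                defined = True
                for (t, k), p in m.outcome[s].items():
                    vt = 0.0 if t == world.goal else V[t]
                    if not np.isfinite(vt):
                        defined = False
                        break
                    v += p * gamma**k * vt
                if defined and v > best:
                    best = v
            if np.isfinite(best) or np.isfinite(V[s]):
                delta = max(delta, abs(best - V[s]) if np.isfinite(best) and np.isfinite(V[s]) else np.inf)
            V[s] = best
        if delta < tol:
            return V
    raise RuntimeError(f"value iteration did not converge within {max_iter} sweeps")


def min_decision_count(world: GridWorld, action_set: ActionSet) -> int:
    """Minimum number of independent decisions from start to goal.

    Breadth-first search on the decision graph in which one primitive
    step and one option launch (jumping to its termination state) each
    cost a single decision.
    """
    opts_at: dict[Cell, list[tuple[Cell, bool]]] = {}
    models = dict(action_set.option_models or {})
    for o in action_set.options:
        if o.id not in models:
            models[o.id] = compute_option_model_exact(world, o)
        m = models[o.id]
        for s, dist in m.outcome.items():
            for (t, _k) in dist:
                opts_at.setdefault(s, []).append((t, True))
    start, goal = world.start, world.goal
    dist = {start: 0}
    frontier = deque([start])
    while frontier:
        s = frontier.popleft()
        succs: list[Cell] = []
        if action_set.primitives:
            succs += world.neighbors(s)
        succs += [t for t, _ in opts_at.get(s, [])]
        for t in succs:
            if t not in dist:
                dist[t] = dist[s] + 1
                if t == goal:
                    return dist[t]
                frontier.append(t)
    raise ValueError("goal unreachable under the given action set")


def moving_average(series: Sequence[float], window: int) -> np.ndarray:
    """Trailing moving average with windows of exactly ``window`` points;
    output length is ``len(series) - window + 1``."""
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(x):
        raise ValueError("window longer than series")
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="valid")
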