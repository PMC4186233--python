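"""Planning under per-step memory failure.

Working-memory limits are modelled as a fixed probability, per unit of
simulation the agent must hold in mind, of "losing its place", which
immediately terminates the planning trial.  Saltatory agents pay one
failure check per decision (an option launch is a single mental step);
flat agents pay one per primitive step, which is the same thing since
every primitive step is a decision.  For the non-saltatory hierarchical
agent — which simulates every primitive step of an executing option —
the default charges one check per simulated primitive step, with a
config switch to charge per decision instead.  This accounting is the
mechanism by which option models confer robustness: fewer mental steps
per trial means a higher chance of reaching the goal before failing.

For comparison with unconstrained planning, each trial also records a
counterfactual ``would_have_taken``: the number of primitive steps the
agent would have needed had it been allowed to continue, obtained by a
greedy rollout (no exploration, no learning) from the failure point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envs import Cell, GridWorld, step
from .planners import ActionSet, Planner, TrialRecord

__all__ = [
    "MemoryLimitConfig",
    "plan_trial_with_memory_limit",
    "survival_probability",
]


@dataclass
class MemoryLimitConfig:
    """Memory-failure protocol.

    Parameters
    ----------
    p_fail:
        Probability of losing one's place, charged per decision (and,
        for step-through option execution, per primitive step when
        ``hierarchical_per_step`` is set).
    counting_rule:
        ``"rollout_to_goal"`` records the would-have-taken counterfactual
        by greedy rollout after a failure; ``"discard"`` leaves it unset.
    hierarchical_per_step:
        Charge the non-saltatory hierarchical agent one failure check per
        simulated primitive step (default) rather than one per decision.
    rollout_cap:
        Primitive-step cap for the counterfactual rollout (default
        ``10 * |S|``); rollouts hitting the cap are marked censored.
    """

    p_fail: float
    counting_rule: str = "rollout_to_goal"
    hierarchical_per_step: bool = True
    rollout_cap: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_fail <= 1.0):
            raise ValueError("p_fail must be in [0, 1]")
        if self.counting_rule not in ("rollout_to_goal", "discard"):
            raise ValueError(f"unknown counting rule {self.counting_rule!r}")


def survival_probability(n_decisions: int, p_fail: float) -> float:
    """Probability that a trial requiring ``n_decisions`` decision steps
    completes before a memory failure: ``(1 - p_fail) ** n_decisions``."""
    if n_decisions < 0:
        raise ValueError("n_decisions must be >= 0")
    return (1.0 - p_fail) ** n_decisions


def _greedy_steps_from(
    planner: Planner, s: Cell, rng: np.random.Generator, cap: int
) -> tuple[int, bool]:
    """Primitive steps of a greedy no-learning rollout from ``s`` to the
    goal; returns (steps, censored)."""
    world = planner.world
    steps = 0
    while s != world.goal and steps < cap:
        i = world.state_index[s]
        col = planner._greedy(i, rng)
        s, _, k, done = planner._transition(col, s, rng)
        steps += k
        if done:
            return steps, False
    return steps, s != world.goal


def plan_trial_with_memory_limit(
    planner: Planner,
    world: GridWorld | None = None,
    action_set: ActionSet | None = None,
    start: Cell | None = None,
    goal: Cell | None = None,
    config: MemoryLimitConfig | None = None,
    rng: np.random.Generator | None = None,
    step_cap: int | None = None,
) -> TrialRecord:
    """One planning trial under the memory-failure protocol.

    Identical to :func:`hrlplan.planners.plan_trial` except that before
    each charged simulation step the trial aborts with probability
    ``config.p_fail``.  Learning updates apply only to transitions fully
    completed before the failure; an option interrupted mid-execution
    contributes no update.  With ``p_fail = 0`` the function reduces
    exactly to unconstrained planning (same rng consumption).
    """
    world = world or planner.world
    action_set = action_set or planner.action_set
    start = start or world.start
    goal = goal or world.goal
    config = config or MemoryLimitConfig(p_fail=0.1)
    rng = rng if rng is not None else np.random.default_rng()
    cap = step_cap or 10 * world.n_states
    p = config.p_fail

    per_step_inside_options = (
        config.hierarchical_per_step
        and action_set.options
        and not action_set.use_option_models
    )

    s = start
    steps = decisions = 0
    failed = False
    while s != goal and steps < cap:
        if p > 0 and rng.random() < p:
            failed = True
            break
        i = world.state_index[s]
        col = planner.select(i, rng)
        decisions += 1
        if col >= planner.n_prim and per_step_inside_options:
            opt = action_set.options[col - planner.n_prim]
            # execute step-by-step, one failure check per primitive step;
            # the launch's check was already paid above (first step)
            s2, k, r = s, 0, 0.0
            interrupted = done = False
            while True:
                if k > 0 and p > 0 and rng.random() < p:
                    interrupted = True
                    break
                a = opt.policy[s2]
                nxt, reward, done = step(world, s2, a, rng)
                if planner.intra_updates:
                    planner.update(
                        world.state_index[s2], a, reward, 1,
                        world.state_index[nxt], done,
                    )
                r += planner.gamma**k * reward
                k += 1
                s2 = nxt
                if done or s2 == opt.subgoal or opt.beta(s2) >= 1.0:
                    break
            steps += k
            s = s2
            if interrupted:
                failed = True  # no update for the unfinished option
                break
            planner.update(i, col, r, k, world.state_index[s], done)
            if done:
                break
        else:
            nxt, r, k, done = planner._transition(col, s, rng, learn=True)
            steps += k
            planner.update(i, col, r, k, world.state_index[nxt], done)
            s = nxt
            if done:
                break
    completed = s == goal and not failed
    would = None
    censored = False
    if config.counting_rule == "rollout_to_goal":
        if completed:
            would = steps
        else:
            # spawned generator: the counterfactual rollout must not
            # perturb the main stream (p_fail = 0 then reproduces
            # unconstrained planning exactly, trial by trial)
            rcap = config.rollout_cap or 10 * world.n_states
            extra, censored = _greedy_steps_from(
                planner, s, rng.spawn(1)[0], rcap
            )
            would = steps + extra
    planner._trials_run += 1
    return TrialRecord(
        trial_index=planner._trials_run - 1,
        primitive_steps=steps,
        decisions=decisions,
        completed=completed,
        would_have_taken=would,
        rollout_censored=censored,
    )
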