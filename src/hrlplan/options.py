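"""Options (temporally extended actions) and option models.

An option bundles an initiation set (where it may be launched), an
internal deterministic policy, a termination function beta, and a
pseudo-reward that defines its subgoal.  An option model summarises an
option for planning: a joint distribution over (termination state,
duration) per initiation state, together with the expected cumulative
discounted reward accrued during execution.  Option models are what
allow a planner to "leap" to an option's outcome without simulating the
intermediate primitive steps.

Doorway options for rooms gridworlds are built automatically: doorway
cells are detected structurally, the map is partitioned into rooms, and
one shortest-path option per (doorway, adjacent room) pair is learned by
value iteration on the option's pseudo-reward problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .envs import (
    ACTIONS,
    ACTION_NAMES,
    Cell,
    GridWorld,
    distance_map,
    step,
)

__all__ = [
    "Option",
    "OptionModel",
    "detect_doorways",
    "room_partition",
    "learn_option_policy",
    "make_doorway_options",
    "compute_option_model_exact",
    "estimate_option_model_mc",
]


@dataclass
class Option:
    """A temporally extended action with a single subgoal.

    ``policy`` maps every non-terminating cell reachable from the
    initiation set to a primitive action.  ``termination`` stores beta
    values; cells absent from the mapping terminate with probability 1
    if outside the initiation set (options may not wander beyond the
    region they were defined for) and 0 otherwise.
    """

    id: str
    initiation_set: frozenset[Cell]
    policy: Mapping[Cell, int]
    subgoal: Cell
    termination: Mapping[Cell, float] = field(default_factory=dict)
    pseudo_reward: Mapping[Cell, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.initiation_set = frozenset(self.initiation_set)
        term = dict(self.termination)
        term[self.subgoal] = 1.0
        for s, b in term.items():
            if not (0.0 <= b <= 1.0):
                raise ValueError(f"termination probability {b} at {s} not in [0,1]")
        self.termination = term

    def beta(self, cell: Cell) -> float:
        """Termination probability at ``cell``."""
        if cell in self.termination:
            return self.termination[cell]
        return 0.0 if cell in self.initiation_set else 1.0

    def available(self, cell: Cell) -> bool:
        return cell in self.initiation_set


@dataclass
class OptionModel:
    """Planning summary of an option.

    ``outcome[s]`` is a distribution ``{(termination_cell, k): p}`` over
    termination states and integer durations ``k >= 1``; ``expected_reward[s]``
    is the mean cumulative gamma-discounted reward accrued while the option
    runs from initiation cell ``s``.
    """

    option_id: str
    outcome: dict[Cell, dict[tuple[Cell, int], float]]
    expected_reward: dict[Cell, float]
    gamma: float

    def __post_init__(self) -> None:
        for s, dist in self.outcome.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"outcome distribution from {s} sums to {total}, not 1"
                )
            for (t, k), p in dist.items():
                if k < 1 or int(k) != k:
                    raise ValueError(f"duration {k} from {s} is not a positive int")
                if p < 0:
                    raise ValueError("negative outcome probability")
            if not np.isfinite(self.expected_reward[s]):
                raise ValueError(f"expected reward from {s} is not finite")

    def sample(self, s: Cell, rng: np.random.Generator) -> tuple[Cell, int]:
        dist = self.outcome[s]
        keys = list(dist)
        if len(keys) == 1:
            return keys[0]
        probs = np.fromiter(dist.values(), dtype=float)
        return keys[rng.choice(len(keys), p=probs / probs.sum())]

    def expected_backup(self, s: Cell, value: Mapping[Cell, float]) -> float:
        """SMDP backup: E[R] + sum over outcomes of gamma^k p V(s')."""
        return self.expected_reward[s] + sum(
            p * self.gamma**k * value[t] for (t, k), p in self.outcome[s].items()
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, dist in sorted(self.outcome.items()):
            for (t, k), p in sorted(dist.items()):
                rows.append(
                    {
                        "option": self.option_id,
                        "init_row": s[0],
                        "init_col": s[1],
                        "term_row": t[0],
                        "term_col": t[1],
                        "duration": k,
                        "probability": p,
                        "expected_reward": self.expected_reward[s],
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# doorway detection


def detect_doorways(world: GridWorld) -> list[Cell]:
    """Structurally detect doorway cells.

    A doorway is a free cell that locally disconnects the map: it has
    exactly two free 4-neighbors lying on opposite sides, and removing
    it disconnects the free cells of its 3x3 neighborhood.  Candidates
    adjacent to other candidates are discarded — chains of such cells
    are corridors, not doorways (a corridor map therefore yields no
    doorways).
    """
    candidates = set()
    for cell in world.free_states:
        nbrs = world.neighbors(cell)
        if len(nbrs) != 2:
            continue
        (r1, c1), (r2, c2) = nbrs
        opposite = (r1 == r2 == cell[0]) or (c1 == c2 == cell[1])
        if not opposite:
            continue
        if _locally_disconnects(world, cell):
            candidates.add(cell)
    doorways = [
        c
        for c in candidates
        if not any(n in candidates for n in world.neighbors(c))
    ]
    return sorted(doorways)


def _locally_disconnects(world: GridWorld, cell: Cell) -> bool:
    r0, c0 = cell
    local = [
        (r, c)
        for r in range(r0 - 1, r0 + 2)
        for c in range(c0 - 1, c0 + 2)
        if (r, c) != cell and world.is_free((r, c))
    ]
    if len(local) < 2:
        return False
    # flood fill within the 3x3 patch using 4-connectivity
    local_set = set(local)
    seen = {local[0]}
    stack = [local[0]]
    while stack:
        r, c = stack.pop()
        for t in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if t in local_set and t not in seen:
                seen.add(t)
                stack.append(t)
    return len(seen) < len(local)


def room_partition(world: GridWorld) -> tuple[dict[Cell, int], list[Cell]]:
    """Partition free cells into rooms separated by doorway cells.

    Returns ``(room_of, doorways)`` where ``room_of`` maps each
    non-doorway free cell to a room id (0-based, ordered by smallest
    member cell).  Doorway cells belong to no room.
    """
    doorways = detect_doorways(world)
    dset = set(doorways)
    room_of: dict[Cell, int] = {}
    rooms: list[list[Cell]] = []
    for cell in world.free_states:
        if cell in dset or cell in room_of:
            continue
        comp = [cell]
        room_of[cell] = -1
        stack = [cell]
        while stack:
            s = stack.pop()
            for t in world.neighbors(s):
                if t not in dset and t not in room_of:
                    room_of[t] = -1
                    comp.append(t)
                    stack.append(t)
        rooms.append(sorted(comp))
    rooms.sort(key=lambda comp: comp[0])
    for rid, comp in enumerate(rooms):
        for cell in comp:
            room_of[cell] = rid
    return room_of, doorways


# ---------------------------------------------------------------------------
# option construction


def learn_option_policy(
    world: GridWorld,
    subgoal: Cell,
    initiation_set: Iterable[Cell],
    option_id: str | None = None,
    pseudo_goal_reward: float = 1.0,
) -> Option:
    """Learn a shortest-path option policy by value iteration.

    The pseudo-reward problem pays ``pseudo_goal_reward`` on entering the
    subgoal and the world's step cost elsewhere, with the subgoal
    absorbing.  The region is restricted to the initiation set plus the
    subgoal; moves leaving the region are treated as bounces.  In a
    deterministic world the greedy policy reaches the subgoal from any
    initiation cell in BFS-shortest-path steps.
    """
    init = frozenset(initiation_set)
    if subgoal not in world.state_index:
        raise ValueError(f"subgoal {subgoal} is not a free cell")
    region = set(init) | {subgoal}
    for cell in region:
        if cell not in world.state_index:
            raise ValueError(f"initiation cell {cell} is not a free cell")

    # restricted deterministic successor: bounce on leaving the region
    def move(s: Cell, a: int) -> Cell:
        t = world._move(s, a)
        return t if t in region else s

    # reachability check (BFS within region)
    dist = {subgoal: 0}
    frontier = [subgoal]
    while frontier:
        nxt_frontier = []
        for s in frontier:
            for t in world.neighbors(s):
                if t in region and t not in dist:
                    dist[t] = dist[s] + 1
                    nxt_frontier.append(t)
        frontier = nxt_frontier
    unreachable = sorted(set(init) - set(dist))
    if unreachable:
        raise ValueError(
            f"subgoal {subgoal} unreachable within region from cells: {unreachable}"
        )

    gamma = world.discount
    cells = sorted(region - {subgoal})
    V = {c: 0.0 for c in region}
    for _ in range(4 * len(region) + 100):
        delta = 0.0
        for s in cells:
            best = -np.inf
            for a in ACTIONS:
                t = move(s, a)
                r = pseudo_goal_reward if t == subgoal else world.step_reward
                v = r + (0.0 if t == subgoal else gamma * V[t])
                best = max(best, v)
            delta = max(delta, abs(best - V[s]))
            V[s] = best
        if delta < 1e-12:
            break
    policy: dict[Cell, int] = {}
    for s in cells:
        best_a, best_v = None, -np.inf
        for a in ACTIONS:  # fixed order -> deterministic ties
            t = move(s, a)
            r = pseudo_goal_reward if t == subgoal else world.step_reward
            v = r + (0.0 if t == subgoal else gamma * V[t])
            if v > best_v + 1e-12:
                best_a, best_v = a, v
        policy[s] = best_a
    pseudo = {subgoal: pseudo_goal_reward}
    return Option(
        id=option_id or f"to_{subgoal[0]}_{subgoal[1]}",
        initiation_set=init,
        policy=policy,
        subgoal=subgoal,
        pseudo_reward=pseudo,
    )


def make_doorway_options(world: GridWorld) -> list[Option]:
    """Build one option per (doorway, adjacent room) pair.

    Each option may be launched anywhere in its room — including the
    room's other doorway cells, so options chain across rooms — and
    drives to its doorway subgoal along a shortest path.
    """
    room_of, doorways = room_partition(world)
    if not doorways:
        warnings.warn("no doorway cells detected; returning no options")
        return []
    n_rooms = len(set(room_of.values()))
    rooms: dict[int, set[Cell]] = {rid: set() for rid in range(n_rooms)}
    for cell, rid in room_of.items():
        rooms[rid].add(cell)
    opts: list[Option] = []
    for d in doorways:
        adj_rooms = sorted({room_of[n] for n in world.neighbors(d) if n in room_of})
        for rid in adj_rooms:
            init = set(rooms[rid])
            # other doorways bordering this room can also launch the option
            for d2 in doorways:
                if d2 != d and any(
                    n in room_of and room_of[n] == rid for n in world.neighbors(d2)
                ):
                    init.add(d2)
            opts.append(
                learn_option_policy(
                    world,
                    subgoal=d,
                    initiation_set=init,
                    option_id=f"room{rid}_to_{d[0]}_{d[1]}",
                )
            )
    return opts


# ---------------------------------------------------------------------------
# option models


def compute_option_model_exact(
    world: GridWorld,
    option: Option,
    tail_mass: float = 1e-9,
    max_horizon: int = 100_000,
) -> OptionModel:
    """Exact option model.

    Deterministic worlds: follow the option policy from each initiation
    cell; the outcome is a point mass on (termination cell, path length)
    and the reward is a finite discounted sum.  Stochastic worlds:
    forward dynamic programming on the absorbing chain over (state,
    elapsed steps), truncated when the surviving probability mass drops
    below ``tail_mass``.
    """
    if world.move_success >= 1.0:
        return _exact_deterministic(world, option)
    return _exact_absorbing_chain(world, option, tail_mass, max_horizon)


def _terminates(world: GridWorld, option: Option, cell: Cell) -> bool:
    # the environment's goal is absorbing regardless of beta
    return cell == world.goal or option.beta(cell) >= 1.0


def _exact_deterministic(world: GridWorld, option: Option) -> OptionModel:
    gamma = world.discount
    outcome: dict[Cell, dict[tuple[Cell, int], float]] = {}
    exp_r: dict[Cell, float] = {}
    for s0 in sorted(option.initiation_set):
        s, k, r = s0, 0, 0.0
        while True:
            if s not in option.policy:
                raise ValueError(
                    f"option {option.id!r}: no policy action at non-terminating "
                    f"cell {s} (started from {s0})"
                )
            t, reward, done = step(world, s, option.policy[s])
            r += gamma**k * reward
            k += 1
            s = t
            if done or _terminates(world, option, s):
                break
            if k > world.n_states:
                raise ValueError(
                    f"option {option.id!r} cycles without terminating from {s0}"
                )
        outcome[s0] = {(s, k): 1.0}
        exp_r[s0] = r
    return OptionModel(option.id, outcome, exp_r, gamma)


def _exact_absorbing_chain(
    world: GridWorld,
    option: Option,
    tail_mass: float,
    max_horizon: int,
) -> OptionModel:
    """Forward DP over the absorbing chain induced by the option policy.

    Transient states are non-terminating cells of the option region; the
    slip model spreads each intended move over the other three actions.
    """
    gamma = world.discount
    p_ok = world.move_success
    p_slip = (1.0 - p_ok) / 3.0

    transient = sorted(
        c for c in option.initiation_set if not _terminates(world, option, c)
    )
    tindex = {c: i for i, c in enumerate(transient)}
    n = len(transient)
    # per transient state: list of (prob, destination cell, reward)
    moves: list[list[tuple[float, Cell]]] = []
    for s in transient:
        if s not in option.policy:
            raise ValueError(f"option {option.id!r}: no policy action at {s}")
        intended = option.policy[s]
        dest: dict[Cell, float] = {}
        for a in ACTIONS:
            p = p_ok if a == intended else p_slip
            t = world._move(s, a)
            dest[t] = dest.get(t, 0.0) + p
        moves.append(list(dest.items()))

    outcome: dict[Cell, dict[tuple[Cell, int], float]] = {}
    exp_r: dict[Cell, float] = {}
    for s0 in sorted(option.initiation_set):
        dist_out: dict[tuple[Cell, int], float] = {}
        r_total = 0.0
        alive = np.zeros(n)
        if s0 in tindex:
            alive[tindex[s0]] = 1.0
            start_k = 0
        else:
            # initiation cell already terminating: the option still must
            # run at least one step (durations are >= 1)
            intended = option.policy.get(s0)
            if intended is None:
                raise ValueError(f"option {option.id!r}: no policy action at {s0}")
            for a in ACTIONS:
                p = p_ok if a == intended else p_slip
                t = world._move(s0, a)
                r_total += p * (
                    world.step_reward + (world.goal_reward if t == world.goal else 0.0)
                )
                if t == world.goal or _terminates(world, option, t) or t not in tindex:
                    key = (t, 1)
                    dist_out[key] = dist_out.get(key, 0.0) + p
                else:
                    alive[tindex[t]] += p
            start_k = 1
        for k in range(start_k, max_horizon):
            mass = alive.sum()
            if mass <= tail_mass:
                break
            new_alive = np.zeros(n)
            for i, s in enumerate(transient):
                p_here = alive[i]
                if p_here == 0.0:
                    continue
                for t, p in moves[i]:
                    pr = p_here * p
                    r_total += pr * gamma**k * (
                        world.step_reward
                        + (world.goal_reward if t == world.goal else 0.0)
                    )
                    if t == world.goal or _terminates(world, option, t) or t not in tindex:
                        key = (t, k + 1)
                        dist_out[key] = dist_out.get(key, 0.0) + pr
                    else:
                        new_alive[tindex[t]] += pr
            alive = new_alive
        residual = alive.sum()
        if residual > tail_mass:
            raise ValueError(
                f"option {option.id!r}: tail mass {residual:.2e} above tolerance "
                f"after {max_horizon} steps from {s0}"
            )
        total = sum(dist_out.values())
        dist_out = {key: p / total for key, p in dist_out.items()}
        outcome[s0] = dist_out
        exp_r[s0] = r_total
    return OptionModel(option.id, outcome, exp_r, gamma)


def estimate_option_model_mc(
    world: GridWorld,
    option: Option,
    n_rollouts: int,
    seed: int | np.random.Generator,
    step_cap: int | None = None,
) -> OptionModel:
    """Monte-Carlo option model: empirical (termination, duration)
    frequencies and mean discounted reward from ``n_rollouts`` executions
    per initiation cell.

    Rollouts exceeding ``step_cap`` (default ``10 * |S|``) without
    terminating are censored; it is an error if every rollout from some
    cell is censored.
    """
    if n_rollouts < 1:
        raise ValueError("n_rollouts must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cap = step_cap or 10 * world.n_states
    gamma = world.discount
    outcome: dict[Cell, dict[tuple[Cell, int], float]] = {}
    exp_r: dict[Cell, float] = {}
    for s0 in sorted(option.initiation_set):
        counts: dict[tuple[Cell, int], int] = {}
        rewards = []
        censored = 0
        for _ in range(n_rollouts):
            s, k, r = s0, 0, 0.0
            while True:
                if s not in option.policy:
                    censored += 1
                    break
                t, reward, done = step(world, s, option.policy[s], rng)
                r += gamma**k * reward
                k += 1
                s = t
                if done or _terminates(world, option, s) or (
                    k >= 1 and s not in option.initiation_set and s != option.subgoal
                ):
                    counts[(s, k)] = counts.get((s, k), 0) + 1
                    rewards.append(r)
                    break
                if k >= cap:
                    censored += 1
                    break
        n_ok = n_rollouts - censored
        if n_ok == 0:
            raise ValueError(
                f"all {n_rollouts} rollouts from {s0} censored at {cap} steps"
            )
        outcome[s0] = {key: c / n_ok for key, c in counts.items()}
        exp_r[s0] = float(np.mean(rewards))
    return OptionModel(option.id, outcome, exp_r, gamma)
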