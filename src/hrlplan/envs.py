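"""Gridworld rooms environments and community graphs.

The central testbed is the "rooms" domain: a discrete gridworld divided
into rooms connected by doorways.  An agent occupies one free cell at a
time and moves with four primitive actions (up, down, left, right); each
step carries a small cost, so optimal behaviour follows a shortest path
from the start cell to the goal cell.

Maps are plain ASCII: ``#`` wall, ``.`` floor, ``S`` start, ``G`` goal.
Coordinates are 0-based ``(row, col)`` with row 0 the top line.

The module also provides a small undirected community-graph container
used for random-walk sequence experiments on graphs with clustered
("community") structure.
"""

from __future__ import annotations

import importlib.resources
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "UP",
    "DOWN",
    "LEFT",
    "RIGHT",
    "ACTIONS",
    "ACTION_NAMES",
    "GridWorld",
    "CommunityGraph",
    "parse_map",
    "load_map",
    "fixture_path",
    "step",
    "shortest_path_length",
    "random_walk_sequence",
    "load_edge_list",
]

UP, DOWN, LEFT, RIGHT = 0, 1, 2, 3
ACTIONS = (UP, DOWN, LEFT, RIGHT)
ACTION_NAMES = {UP: "up", DOWN: "down", LEFT: "left", RIGHT: "right"}
_DELTAS = {UP: (-1, 0), DOWN: (1, 0), LEFT: (0, -1), RIGHT: (0, 1)}

Cell = tuple[int, int]


class MapError(ValueError):
    """Raised for malformed or invalid ASCII maps."""


@dataclass
class GridWorld:
    """A deterministic (optionally noisy) gridworld MDP.

    Parameters
    ----------
    width, height:
        Grid dimensions in cells.
    walls:
        Set of ``(row, col)`` wall cells.
    start, goal:
        Free cells; the goal is absorbing.
    step_reward:
        Reward for every primitive step (non-positive; default -1 so
        that negated returns under gamma=1 equal step counts).
    goal_reward:
        Extra reward collected on entering the goal.
    discount:
        Discount factor gamma used by planners and option models.
    move_success:
        Probability that the intended move is executed; with probability
        ``1 - move_success`` one of the other three actions is executed
        instead (uniformly).  Default 1.0 (deterministic).
    """

    width: int
    height: int
    walls: frozenset[Cell]
    start: Cell
    goal: Cell
    step_reward: float = -1.0
    goal_reward: float = 0.0
    discount: float = 0.95
    move_success: float = 1.0

    free_states: list[Cell] = field(init=False, repr=False)
    state_index: dict[Cell, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.discount <= 1.0):
            raise ValueError(f"discount must be in (0, 1], got {self.discount}")
        if self.step_reward > 0:
            raise ValueError("step_reward must be <= 0")
        if not (0.0 < self.move_success <= 1.0):
            raise ValueError("move_success must be in (0, 1]")
        self.walls = frozenset(self.walls)
        self.free_states = [
            (r, c)
            for r in range(self.height)
            for c in range(self.width)
            if (r, c) not in self.walls
        ]
        self.state_index = {s: i for i, s in enumerate(self.free_states)}
        for name in ("start", "goal"):
            cell = getattr(self, name)
            if cell not in self.state_index:
                raise MapError(f"{name} cell {cell} is not a free cell")
        self._check_connected()
        # deterministic next-state table: next_state[i, a] -> state index
        n = len(self.free_states)
        self._next = np.empty((n, 4), dtype=np.intp)
        for i, s in enumerate(self.free_states):
            for a in ACTIONS:
                self._next[i, a] = self.state_index[self._move(s, a)]

    def _check_connected(self) -> None:
        seen = {self.start}
        frontier = deque([self.start])
        while frontier:
            s = frontier.popleft()
            for a in ACTIONS:
                t = self._move(s, a)
                if t not in seen:
                    seen.add(t)
                    frontier.append(t)
        unreachable = sorted(set(self.free_states) - seen)
        if unreachable:
            raise MapError(
                f"free cells unreachable from start {self.start}: {unreachable}"
            )

    def _move(self, state: Cell, action: int) -> Cell:
        dr, dc = _DELTAS[action]
        r, c = state[0] + dr, state[1] + dc
        if r < 0 or r >= self.height or c < 0 or c >= self.width:
            return state
        if (r, c) in self.walls:
            return state
        return (r, c)

    @property
    def n_states(self) -> int:
        return len(self.free_states)

    def is_free(self, cell: Cell) -> bool:
        return cell in self.state_index

    def neighbors(self, cell: Cell) -> list[Cell]:
        """Distinct free 4-neighbors actually adjacent (excluding bounces)."""
        out = []
        for a in ACTIONS:
            t = self._move(cell, a)
            if t != cell:
                out.append(t)
        return out

    def to_graph(self) -> nx.Graph:
        """Free-cell adjacency graph (4-connectivity)."""
        g = nx.Graph()
        g.add_nodes_from(self.free_states)
        for s in self.free_states:
            for t in self.neighbors(s):
                g.add_edge(s, t)
        return g

    def next_state_index(self, i: int, a: int) -> int:
        return int(self._next[i, a])


def parse_map(
    text: str,
    *,
    step_reward: float = -1.0,
    goal_reward: float = 0.0,
    discount: float = 0.95,
    move_success: float = 1.0,
) -> GridWorld:
    """Parse an ASCII map into a validated :class:`GridWorld`.

    Allowed characters: ``#`` (wall), ``.`` (floor), ``S`` (start),
    ``G`` (goal).  Rows must all have the same length.
    """
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise MapError("empty map")
    width = len(lines[0])
    if any(len(ln) != width for ln in lines):
        raise MapError("map is not rectangular")
    walls: set[Cell] = set()
    starts: list[Cell] = []
    goals: list[Cell] = []
    for r, ln in enumerate(lines):
        for c, ch in enumerate(ln):
            if ch == "#":
                walls.add((r, c))
            elif ch == "S":
                starts.append((r, c))
            elif ch == "G":
                goals.append((r, c))
            elif ch != ".":
                raise MapError(f"invalid character {ch!r} at {(r, c)}")
    if len(starts) != 1:
        raise MapError(f"map must contain exactly one 'S', found {len(starts)}")
    if len(goals) != 1:
        raise MapError(f"map must contain exactly one 'G', found {len(goals)}")
    return GridWorld(
        width=width,
        height=len(lines),
        walls=frozenset(walls),
        start=starts[0],
        goal=goals[0],
        step_reward=step_reward,
        goal_reward=goal_reward,
        discount=discount,
        move_success=move_success,
    )


def fixture_path(name: str):
    """Path to a shipped fixture file (map or edge list)."""
    return importlib.resources.files("hrlplan.fixtures") / name


def load_map(name_or_path, **kwargs) -> GridWorld:
    """Load a map from a shipped fixture name (e.g. ``rooms_default.map``)
    or a filesystem path."""
    import os

    p = str(name_or_path)
    if os.path.exists(p):
        text = open(p).read()
    else:
        text = fixture_path(p).read_text()
    return parse_map(text, **kwargs)


def step(
    world: GridWorld,
    state: Cell,
    action: int,
    rng: np.random.Generator | None = None,
) -> tuple[Cell, float, bool]:
    """One primitive transition.

    Moving into a wall or off-grid leaves the state unchanged ("bounce").
    Reward is ``step_reward``, plus ``goal_reward`` when the goal is
    entered, which also terminates the episode.  In noisy worlds
    (``move_success < 1``) an rng must be supplied; the intended action is
    replaced by one of the other three with total probability
    ``1 - move_success``.
    """
    if state not in world.state_index:
        raise ValueError(f"state {state} is not a free cell")
    if action not in ACTIONS:
        raise ValueError(f"unknown action {action}")
    if world.move_success < 1.0:
        if rng is None:
            raise ValueError("stochastic world requires an rng")
        if rng.random() > world.move_success:
            others = [a for a in ACTIONS if a != action]
            action = others[rng.integers(3)]
    nxt = world._move(state, action)
    done = nxt == world.goal
    reward = world.step_reward + (world.goal_reward if done else 0.0)
    return nxt, reward, done


def shortest_path_length(world: GridWorld, source: Cell, target: Cell) -> int:
    """BFS distance (number of primitive steps) between two free cells."""
    for cell in (source, target):
        if cell not in world.state_index:
            raise ValueError(f"cell {cell} is not a free cell")
    if source == target:
        return 0
    dist = {source: 0}
    frontier = deque([source])
    while frontier:
        s = frontier.popleft()
        for t in world.neighbors(s):
            if t not in dist:
                dist[t] = dist[s] + 1
                if t == target:
                    return dist[t]
                frontier.append(t)
    raise ValueError(f"{target} unreachable from {source}")


def distance_map(world: GridWorld, target: Cell) -> dict[Cell, int]:
    """BFS distances from every free cell to ``target`` (may be partial
    if cells cannot reach the target)."""
    dist = {target: 0}
    frontier = deque([target])
    while frontier:
        s = frontier.popleft()
        for t in world.neighbors(s):
            if t not in dist:
                dist[t] = dist[s] + 1
                frontier.append(t)
    return dist


# ---------------------------------------------------------------------------
# community graphs


@dataclass
class CommunityGraph:
    """Connected undirected graph with optional per-vertex community labels."""

    graph: nx.Graph
    community_labels: Mapping | None = None

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")
        if self.graph.number_of_nodes() > 0 and not nx.is_connected(self.graph):
            raise ValueError("community graph must be connected")

    @property
    def vertices(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {frozenset(e) for e in self.graph.edges}

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic uniform random-walk transition matrix, rows and
        columns ordered by :attr:`vertices`."""
        verts = self.vertices
        idx = {v: i for i, v in enumerate(verts)}
        T = np.zeros((len(verts), len(verts)))
        for v in verts:
            nbrs = list(self.graph.neighbors(v))
            if not nbrs:
                raise ValueError(f"vertex {v} is isolated")
            for u in nbrs:
                T[idx[v], idx[u]] = 1.0 / len(nbrs)
        return T


def load_edge_list(name_or_path) -> CommunityGraph:
    """Read a whitespace-delimited edge list.

    Each non-comment line is ``u v [community]`` where the optional third
    column labels the community both endpoints belong to (``-`` for
    between-community bridge edges).
    """
    import os

    p = str(name_or_path)
    text = open(p).read() if os.path.exists(p) else fixture_path(p).read_text()
    g = nx.Graph()
    labels: dict = {}
    for ln in text.splitlines():
        ln = ln.split("#")[0].strip()
        if not ln:
            continue
        parts = ln.split()
        if len(parts) not in (2, 3):
            raise ValueError(f"bad edge-list line: {ln!r}")
        u, v = (int(x) if x.isdigit() else x for x in parts[:2])
        g.add_edge(u, v)
        if len(parts) == 3 and parts[2] != "-":
            lab = int(parts[2]) if parts[2].isdigit() else parts[2]
            labels[u] = lab
            labels[v] = lab
    return CommunityGraph(graph=g, community_labels=labels or None)


def random_walk_sequence(
    graph: CommunityGraph,
    length: int,
    seed: int | np.random.Generator,
    start=None,
) -> list:
    """Uniform random walk of ``length`` vertices over the graph.

    Each successive vertex is a uniformly chosen neighbor of the previous
    one, so every consecutive pair in the output is an edge.  The walk is
    reproducible given ``seed``; ``start`` defaults to a vertex chosen
    uniformly by the same rng.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    verts = graph.vertices
    if start is None:
        start = verts[rng.integers(len(verts))]
    if start not in graph.graph:
        raise ValueError(f"unknown start vertex {start}")
    if graph.graph.degree(start) == 0:
        raise ValueError(f"start vertex {start} is isolated")
    walk = [start]
    cur = start
    for _ in range(length - 1):
        nbrs = sorted(graph.graph.neighbors(cur))
        cur = nbrs[rng.integers(len(nbrs))]
        walk.append(cur)
    return walk
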