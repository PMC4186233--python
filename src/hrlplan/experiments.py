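"""End-to-end experiments: learning curves, memory-limited planning, and
successor-representation structure recovery.

Each experiment is a pure function of its config (all randomness flows
from ``seed_base``), emits tidy CSV files, and returns the same tables as
DataFrames.  Curves follow the convention: mean across runs first, then a
trailing moving average over trials.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .envs import GridWorld, load_map, shortest_path_length
from .memory_limits import MemoryLimitConfig, plan_trial_with_memory_limit
from .options import make_doorway_options, room_partition
from .planners import (
    ActionSet,
    Planner,
    greedy_rollout,
    min_decision_count,
    moving_average,
    plan_trial,
)
from .sr_discovery import (
    cluster_states,
    embed_mds,
    identify_bottlenecks,
    successor_representation,
    transition_model_from_exploration,
)

__all__ = [
    "ExperimentConfig",
    "build_action_sets",
    "planning_curves",
    "memory_limited_curves",
    "sr_structure",
]

AGENTS = ("flat", "hierarchical", "saltatory")


@dataclass
class ExperimentConfig:
    """Shared configuration for all experiments.

    Defaults restate the reference protocol: 100 independent runs of 100
    planning trials each, curves smoothed with a 10-step moving average,
    memory failure probability 0.1 per charged step, gamma 0.95.
    """

    map_path: str = "rooms_default.map"
    agents: tuple[str, ...] = AGENTS
    n_trials: int = 100
    n_runs: int = 100
    seed_base: int = 0
    p_fail: float = 0.1
    smoothing_window: int = 10
    gamma: float = 0.95
    alpha: float = 1.0
    epsilon: float = 0.1
    exploration_steps: int = 100_000
    sr_gamma: float = 0.95
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.n_trials < self.smoothing_window:
            raise ValueError("n_trials must be >= smoothing_window")
        unknown = set(self.agents) - set(AGENTS)
        if unknown:
            raise ValueError(f"unknown agents: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "agents" in raw:
            raw["agents"] = tuple(raw["agents"])
        return cls(**raw)

    def seeds(self) -> list[int]:
        return [self.seed_base + i for i in range(self.n_runs)]

    def load_world(self) -> GridWorld:
        return load_map(self.map_path, discount=self.gamma)


def build_action_sets(
    world: GridWorld, agents: Sequence[str] = AGENTS
) -> dict[str, ActionSet]:
    opts = make_doorway_options(world)
    table = {
        "flat": lambda: ActionSet.flat(),
        "hierarchical": lambda: ActionSet.hierarchical(opts),
        "saltatory": lambda: ActionSet.saltatory(world, opts),
    }
    return {name: table[name]() for name in agents}


def _write(df: pd.DataFrame, output_dir: str | None, name: str) -> None:
    if output_dir is not None:
        os.makedirs(output_dir, exist_ok=True)
        df.to_csv(os.path.join(output_dir, name), index=False)


def _smooth_curves(
    raw: pd.DataFrame, value_cols: Sequence[str], window: int
) -> pd.DataFrame:
    """Mean across runs per trial, then trailing moving average."""
    out = {}
    for agent, grp in raw.groupby("agent"):
        means = grp.groupby("trial")[list(value_cols)].mean().sort_index()
        for col in value_cols:
            sm = moving_average(means[col].to_numpy(), window)
            out[f"{agent}_{col}"] = sm
    trials = np.arange(window - 1, window - 1 + len(next(iter(out.values()))))
    return pd.DataFrame({"trial": trials, **out})


def planning_curves(
    config: ExperimentConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unconstrained planning performance of the configured agents.

    All agents share the same per-run seeds.  Returns ``(curves, raw)``:
    ``raw`` has one row per (agent, run, trial); ``curves`` holds the
    smoothed mean step and decision counts per agent plus two oracle
    reference lines — the minimum number of primitive actions to the
    goal (``min_steps``) and the minimum number of decisions when option
    models are available (``min_decisions``).
    """
    world = config.load_world()
    action_sets = build_action_sets(world, config.agents)
    rows = []
    for agent, aset in action_sets.items():
        for run, seed in enumerate(config.seeds()):
            rng = np.random.default_rng(seed)
            planner = Planner(
                world, aset, alpha=config.alpha, epsilon=config.epsilon
            )
            for t in range(config.n_trials):
                rec = plan_trial(planner, rng=rng)
                rows.append(
                    {
                        "agent": agent,
                        "run": run,
                        "trial": t,
                        "primitive_steps": rec.primitive_steps,
                        "decisions": rec.decisions,
                        "completed": rec.completed,
                    }
                )
    raw = pd.DataFrame(rows)
    curves = _smooth_curves(
        raw, ["primitive_steps", "decisions"], config.smoothing_window
    )
    curves["min_steps"] = shortest_path_length(world, world.start, world.goal)
    if "saltatory" in action_sets:
        curves["min_decisions"] = min_decision_count(
            world, action_sets["saltatory"]
        )
    _write(raw, config.output_dir, "planning_raw.csv")
    _write(curves, config.output_dir, "planning_curves.csv")
    return curves, raw


def memory_limited_curves(
    config: ExperimentConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Planning performance under the memory-failure protocol.

    As :func:`planning_curves`, but each trial aborts with probability
    ``p_fail`` per charged simulation step, and the reported step counts
    are the counterfactual ``would_have_taken`` (greedy rollout to the
    goal from the failure point).  Returns ``(curves, raw, completion)``
    where ``completion`` holds per-agent per-run completion rates.
    With ``p_fail = 0`` the raw table coincides with the unconstrained
    experiment for the same seeds.
    """
    world = config.load_world()
    action_sets = build_action_sets(world, config.agents)
    mem = MemoryLimitConfig(p_fail=config.p_fail)
    rows = []
    for agent, aset in action_sets.items():
        for run, seed in enumerate(config.seeds()):
            rng = np.random.default_rng(seed)
            planner = Planner(
                world, aset, alpha=config.alpha, epsilon=config.epsilon
            )
            for t in range(config.n_trials):
                rec = plan_trial_with_memory_limit(
                    planner, config=mem, rng=rng
                )
                rows.append(
                    {
                        "agent": agent,
                        "run": run,
                        "trial": t,
                        "p_fail": config.p_fail,
                        "primitive_steps": rec.primitive_steps,
                        "decisions": rec.decisions,
                        "completed": rec.completed,
                        "would_have_taken": rec.would_have_taken,
                        "rollout_censored": rec.rollout_censored,
                    }
                )
    raw = pd.DataFrame(rows)
    curves = _smooth_curves(
        raw, ["would_have_taken", "decisions"], config.smoothing_window
    )
    curves["min_steps"] = shortest_path_length(world, world.start, world.goal)
    completion = (
        raw.groupby(["agent", "run"])["completed"]
        .mean()
        .rename("completion_rate")
        .reset_index()
    )
    _write(raw, config.output_dir, "memory_raw.csv")
    _write(curves, config.output_dir, "memory_curves.csv")
    _write(completion, config.output_dir, "memory_completion.csv")
    return curves, raw, completion


def sr_structure(config: ExperimentConfig) -> pd.DataFrame:
    """Latent learning -> successor representation -> structure recovery.

    Explores the map with uniformly random actions, estimates the
    random-walk transition matrix, computes the SR, clusters its rows
    (cluster count chosen by silhouette), embeds them with classical
    MDS, and flags bottleneck states.  Returns one row per free cell:
    ``row, col, cluster, silhouette, x, y, is_bottleneck, is_doorway,
    room``.
    """
    from sklearn.metrics import silhouette_samples

    world = config.load_world()
    T, states = transition_model_from_exploration(
        world, config.exploration_steps, config.seed_base
    )
    sr = successor_representation(T, config.sr_gamma, states=states)
    labels, chosen_k = cluster_states(sr)
    sil = silhouette_samples(sr.matrix, labels)
    coords = embed_mds(sr)
    bottlenecks = set(identify_bottlenecks(sr, labels))
    room_of, doorways = room_partition(world)
    df = pd.DataFrame(
        {
            "row": [s[0] for s in states],
            "col": [s[1] for s in states],
            "cluster": labels,
            "silhouette": sil,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "is_bottleneck": [s in bottlenecks for s in states],
            "is_doorway": [s in set(doorways) for s in states],
            "room": [room_of.get(s, -1) for s in states],
        }
    )
    df.attrs["chosen_k"] = int(chosen_k)
    _write(df, config.output_dir, "sr_structure.csv")
    return df
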