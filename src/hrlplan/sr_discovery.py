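"""Successor-representation subgoal discovery.

Under a fixed policy with transition matrix ``T``, the successor
representation (SR) is ``M = (I - gamma T)^{-1}``: entry ``M[i, j]`` is
the expected discounted future occupancy of state ``j`` starting from
``i``.  Rows of M are predictive codes — states that predict similar
futures have similar rows — so the community structure of an environment
(rooms, graph clusters) appears directly as cluster structure among SR
rows, and bottleneck states (doorways, bridge vertices) appear as
isolated points between the clusters.  This gives a reward-free route to
subgoal discovery: explore, build a transition model, compute the SR,
cluster, and nominate the poorly-clustered states as subgoals.

The SR here is always computed for the uniform random-walk policy, as
acquired by latent (reward-free) learning; there is no absorbing goal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import silhouette_samples, silhouette_score

from .envs import ACTIONS, Cell, GridWorld

__all__ = [
    "SuccessorRepresentation",
    "successor_representation",
    "random_walk_transition_matrix",
    "transition_model_from_exploration",
    "cluster_states",
    "identify_bottlenecks",
    "embed_mds",
]


@dataclass
class SuccessorRepresentation:
    """Discounted expected-occupancy matrix under a fixed policy."""

    states: list
    matrix: np.ndarray
    gamma: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.states):
            raise ValueError("matrix must be square over the state list")
        if (m < -1e-12).any():
            raise ValueError("SR entries must be non-negative")
        self.matrix = m


def successor_representation(
    T: np.ndarray, gamma: float, states: Sequence | None = None
) -> SuccessorRepresentation:
    """Solve ``(I - gamma T) M = I`` for the SR of a row-stochastic T.

    Row sums of M equal ``1 / (1 - gamma)`` whenever T is row-stochastic.
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("T must be square")
    if not (0.0 < gamma < 1.0):
        raise ValueError("gamma must be in (0, 1)")
    rowsums = T.sum(axis=1)
    if np.abs(rowsums - 1.0).max() > 1e-9:
        raise ValueError("T is not row-stochastic")
    n = T.shape[0]
    M = scipy.linalg.solve(np.eye(n) - gamma * T, np.eye(n))
    states = list(states) if states is not None else list(range(n))
    return SuccessorRepresentation(states=states, matrix=M, gamma=gamma)


def random_walk_transition_matrix(world: GridWorld) -> np.ndarray:
    """Exact state-to-state transition matrix of the uniform random walk
    over primitive actions (bounces included, goal not absorbing)."""
    n = world.n_states
    T = np.zeros((n, n))
    for i in range(n):
        for a in ACTIONS:
            T[i, world.next_state_index(i, a)] += 0.25
    return T


def transition_model_from_exploration(
    world: GridWorld,
    n_steps: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, list[Cell]]:
    """Latent learning: estimate the random-walk transition matrix from a
    single exploratory trajectory of uniformly random actions.

    Returns ``(T_hat, states)`` with rows renormalized to empirical
    frequencies.  Raises if any state was never visited as a source
    (increase ``n_steps``).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = world.n_states
    counts = np.zeros((n, n))
    i = world.state_index[world.start]
    actions = rng.integers(0, 4, size=n_steps)
    if world.move_success < 1.0:
        slip = rng.random(size=n_steps)
        repl = rng.integers(0, 3, size=n_steps)
    for t in range(n_steps):
        a = int(actions[t])
        if world.move_success < 1.0 and slip[t] > world.move_success:
            a = [b for b in ACTIONS if b != a][repl[t]]
        j = world.next_state_index(i, a)
        counts[i, j] += 1
        i = j
    visited = counts.sum(axis=1)
    unvisited = [world.free_states[i] for i in np.flatnonzero(visited == 0)]
    if unvisited:
        raise ValueError(
            f"{len(unvisited)} states unvisited after {n_steps} steps: "
            f"{unvisited[:10]}{'...' if len(unvisited) > 10 else ''}"
        )
    T = counts / visited[:, None]
    return T, list(world.free_states)


def cluster_states(
    sr: SuccessorRepresentation,
    k_candidates: Sequence[int] = range(2, 13),
    method: str = "ward",
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Cluster SR rows and select the number of clusters by silhouette.

    Ward agglomerative clustering (deterministic) on Euclidean distances
    between rows of M; the candidate k with the highest mean silhouette
    wins (smallest k on ties).  ``method="kmeans"`` is available with a
    fixed seed.
    """
    M = sr.matrix
    n = M.shape[0]
    ks = [k for k in k_candidates]
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise ValueError("k candidates must lie within [2, n_states - 1]")
    row_spread = np.ptp(M, axis=0)
    if row_spread.max() < 1e-12:
        raise ValueError("degenerate SR: all rows identical")
    best = (-np.inf, None, None)
    for k in ks:
        if method == "ward":
            labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(M)
        elif method == "kmeans":
            labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(M)
        else:
            raise ValueError(f"unknown clustering method {method!r}")
        score = silhouette_score(M, labels)
        if score > best[0] + 1e-12:
            best = (score, k, labels)
    _, chosen_k, labels = best
    return labels, chosen_k


def identify_bottlenecks(
    sr: SuccessorRepresentation,
    labels: np.ndarray,
    threshold: float = 0.05,
) -> list:
    """States that sit between clusters in SR space.

    A state is a bottleneck candidate if its silhouette value is below
    ``threshold`` or it forms a singleton cluster.  If the clustering as
    a whole is unstructured (mean silhouette below the threshold, as for
    a fully connected graph) there are no communities to be between, and
    the list is empty.  Results are sorted by ascending silhouette.
    """
    M = sr.matrix
    labels = np.asarray(labels)
    sil = silhouette_samples(M, labels)
    if sil.mean() < threshold:
        return []
    counts = {lab: int((labels == lab).sum()) for lab in np.unique(labels)}
    flagged = [
        i
        for i in range(len(labels))
        if sil[i] < threshold or counts[labels[i]] == 1
    ]
    flagged.sort(key=lambda i: sil[i])
    return [sr.states[i] for i in flagged]


def embed_mds(sr: SuccessorRepresentation, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling of SR rows.

    Embeds pairwise Euclidean distances between rows of M; coordinates
    are centered at the origin and defined up to rotation/reflection.
    Falls back (with a warning) to fewer dimensions if the doubly
    centered matrix has insufficient positive eigenvalues.
    """
    M = sr.matrix
    n = M.shape[0]
    if n < 3:
        raise ValueError("need at least 3 states to embed")
    sq = ((M[:, None, :] - M[None, :, :]) ** 2).sum(-1)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, 1e-9 * abs(vals[0]))
    avail = int(pos.sum())
    if avail < n_components:
        warnings.warn(
            f"distance matrix supports only {avail} MDS dimensions; "
            f"requested {n_components}"
        )
        n_components = max(avail, 1)
    coords = vecs[:, :n_components] * np.sqrt(np.maximum(vals[:n_components], 0.0))
    return coords - coords.mean(axis=0)
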