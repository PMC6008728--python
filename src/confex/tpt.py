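"""Transition path theory on Markov state models.

Given a transition matrix with stationary distribution π and disjoint
source/sink sets A and B, the forward committor q⁺_i is the probability
that a trajectory started in i reaches B before A; it solves the linear
system q_i = Σ_j T_ij q_j on the intermediate states with boundary
values q(A)=0, q(B)=1.  The backward committor comes from the
time-reversed chain and equals 1−q⁺ for reversible models.  Reactive
flux f_ij = π_i q⁻_i T_ij q⁺_j decomposes A→B transitions into
pathways; here the decomposition peels off widest (max-bottleneck)
paths deterministically, which reproduces the flux-accounting style of
pathway tables.

Transition-path durations are also extracted directly from labeled
trajectories: one reactive segment runs from the last frame in the
source set to the first frame in the sink set.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .msm import StateTraj, TransitionModel

__all__ = [
    "CommittorVector",
    "FluxNetwork",
    "PathwaySet",
    "TptSample",
    "committors",
    "reactive_flux",
    "decompose_pathways",
    "extract_transition_paths",
    "core_labels",
    "order_states_by_committor",
]


@dataclass
class CommittorVector:
    q_plus: np.ndarray
    q_minus: np.ndarray
    source: np.ndarray
    sink: np.ndarray

    def __post_init__(self) -> None:
        for q in (self.q_plus, self.q_minus):
            if np.any(q < -1e-10) or np.any(q > 1 + 1e-10):
                raise ValueError("committors must lie in [0, 1]")


@dataclass
class FluxNetwork:
    gross: np.ndarray
    net: np.ndarray
    total: float
    source: np.ndarray
    sink: np.ndarray


@dataclass
class PathwaySet:
    """Pathways ordered by decreasing flux with their share of the total."""

    paths: list[tuple[tuple[int, ...], float]]
    total_flux: float
    residual_flux: float

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.paths]) / self.total_flux


@dataclass
class TptSample:
    durations: np.ndarray
    directions: np.ndarray  # +1 forward (A->B), -1 backward

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if np.any(self.durations <= 0):
            raise ValueError("transition-path durations must be positive")

    @property
    def mean(self) -> float:
        return float(np.mean(self.durations)) if len(self.durations) else np.nan

    @property
    def range(self) -> tuple[float, float]:
        if not len(self.durations):
            return (np.nan, np.nan)
        return float(np.min(self.durations)), float(np.max(self.durations))

    def __len__(self) -> int:
        return len(self.durations)


def _validate_sets(n, a, b):
    a = np.unique(np.asarray(a, dtype=int))
    b = np.unique(np.asarray(b, dtype=int))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("source and sink sets must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("source and sink sets must be disjoint")
    if a.min() < 0 or a.max() >= n or b.min() < 0 or b.max() >= n:
        raise ValueError("state ids outside the model")
    return a, b


def committors(model: TransitionModel, source, sink) -> CommittorVector:
    """Forward and backward committors for source set A and sink set B."""
    n = model.n_states
    a, b = _validate_sets(n, source, sink)
    t = model.transition_mat
    inter = np.setdiff1d(np.arange(n), np.concatenate([a, b]))

    # reachability: every intermediate must be able to reach B
    reach = np.zeros(n, dtype=bool)
    reach[b] = True
    frontier = list(b)
    incoming = [np.flatnonzero(t[:, j] > 0) for j in range(n)]
    while frontier:
        j = frontier.pop()
        for i in incoming[j]:
            if not reach[i]:
                reach[i] = True
                frontier.append(i)
    dead = np.setdiff1d(np.flatnonzero(~reach), a)
    if dead.size:
        raise ValueError(f"sink unreachable from states {dead.tolist()}")

    q_plus = np.zeros(n)
    q_plus[b] = 1.0
    if inter.size:
        t_ii = t[np.ix_(inter, inter)]
        rhs = t[np.ix_(inter, b)].sum(axis=1)
        q_plus[inter] = np.linalg.solve(np.eye(len(inter)) - t_ii, rhs)

    # backward committor via the time-reversed chain
    pi = model.stationary
    with np.errstate(divide="ignore", invalid="ignore"):
        t_rev = (t.T * pi[None, :]) / pi[:, None]
    t_rev = np.nan_to_num(t_rev)
    q_minus = np.zeros(n)
    q_minus[a] = 1.0
    if inter.size:
        t_ii = t_rev[np.ix_(inter, inter)]
        rhs = t_rev[np.ix_(inter, a)].sum(axis=1)
        q_minus[inter] = np.linalg.solve(np.eye(len(inter)) - t_ii, rhs)

    q_plus = np.clip(q_plus, 0.0, 1.0)
    q_minus = np.clip(q_minus, 0.0, 1.0)
    return CommittorVector(q_plus=q_plus, q_minus=q_minus, source=a, sink=b)


def reactive_flux(model: TransitionModel, comm: CommittorVector) -> FluxNetwork:
    """Reactive flux f_ij = π_i q⁻_i T_ij q⁺_j and its net part.

    The net flux f⁺ = max(f − fᵀ, 0) has zero divergence at
    intermediate states; the total A→B flux equals the net flux out of
    the source set."""
    pi = model.stationary
    t = model.transition_mat
    gross = (pi * comm.q_minus)[:, None] * t * comm.q_plus[None, :]
    np.fill_diagonal(gross, 0.0)
    net = np.maximum(gross - gross.T, 0.0)
    total = float(net[comm.source, :].sum() - net[:, comm.source].sum())
    return FluxNetwork(gross=gross, net=net, total=total, source=comm.source, sink=comm.sink)


def _widest_path(net: np.ndarray, source, sink):
    """Max-bottleneck path from any source to any sink state.

    Modified Dijkstra maximizing the minimum edge flux along the path;
    ties broken lexicographically by state index for determinism."""
    n = net.shape[0]
    width = np.full(n, -np.inf)
    parent = np.full(n, -1, dtype=int)
    in_sink = np.zeros(n, dtype=bool)
    in_sink[sink] = True
    heap = []
    for s in sorted(source.tolist()):
        width[s] = np.inf
        heapq.heappush(heap, (-np.inf, s))
    done = np.zeros(n, dtype=bool)
    while heap:
        neg_w, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        if in_sink[u]:
            path = [u]
            while parent[path[-1]] >= 0:
                path.append(parent[path[-1]])
            return tuple(reversed(path)), float(width[u])
        for v in np.flatnonzero(net[u] > 0):
            w_new = min(width[u], net[u, v])
            if w_new > width[v] and not done[v]:
                width[v] = w_new
                parent[v] = u
                heapq.heappush(heap, (-w_new, v))
    return None, 0.0


def decompose_pathways(
    flux: FluxNetwork,
    stop_fraction: float = 0.999,
    max_paths: int = 10_000,
) -> PathwaySet:
    """Iterative widest-path decomposition of the net reactive flux.

    Repeatedly finds the A→B path whose minimum edge flux (bottleneck)
    is largest, records it with the bottleneck flux, subtracts that flux
    along the path and repeats until the accumulated fraction reaches
    ``stop_fraction``.  Each iteration strictly decreases the remaining
    flux, so termination is guaranteed."""
    if not 0 < stop_fraction <= 1:
        raise ValueError("stop_fraction must lie in (0, 1]")
    residual = flux.net.copy()
    total = flux.total
    if total <= 0:
        raise ValueError("no reactive flux between source and sink")
    paths: list[tuple[tuple[int, ...], float]] = []
    accumulated = 0.0
    while accumulated < stop_fraction * total and len(paths) < max_paths:
        path, bottleneck = _widest_path(residual, flux.source, flux.sink)
        if path is None or bottleneck <= 0:
            break
        for i, j in zip(path[:-1], path[1:]):
            residual[i, j] -= bottleneck
        paths.append((path, bottleneck))
        accumulated += bottleneck
    return PathwaySet(paths=paths, total_flux=total, residual_flux=float(total - accumulated))


def core_labels(features, a_center, b_center, radius: float) -> np.ndarray:
    """Label continuous frames by core membership: 0 in A, 1 in B, 2 neither.

    Cores are discs of the given radius around each center; frames
    outside both cores keep the transition region label 2."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    d_a = np.linalg.norm(x - np.asarray(a_center)[None, :], axis=1)
    d_b = np.linalg.norm(x - np.asarray(b_center)[None, :], axis=1)
    labels = np.full(len(x), 2, dtype=np.int64)
    labels[d_a <= radius] = 0
    labels[d_b <= radius] = 1
    both = (d_a <= radius) & (d_b <= radius)
    if np.any(both):
        raise ValueError("cores overlap: decrease the radius")
    return labels


def extract_transition_paths(
    traj: StateTraj,
    source,
    sink,
    both_directions: bool = True,
) -> TptSample:
    """Durations of reactive segments between two state sets.

    A forward transition path runs from the last frame in A to the
    first subsequent frame in B with no A or B frames in between; its
    duration is (t_B − t_A)·dt.  B→A segments are pooled by default and
    tagged with direction −1.  Strict set membership defines the
    endpoints; use :func:`core_labels` to build a labeled trajectory
    from continuous features."""
    a = set(int(s) for s in np.atleast_1d(source))
    b = set(int(s) for s in np.atleast_1d(sink))
    if a & b:
        raise ValueError("source and sink sets must be disjoint")
    durations = []
    directions = []
    last_set = None  # 0 if last core visited was A, 1 if B
    last_exit = -1
    for t_idx, s in enumerate(np.asarray(traj.states)):
        s = int(s)
        if s in a:
            if last_set == 1 and both_directions:
                durations.append((t_idx - last_exit) * traj.dt)
                directions.append(-1)
            last_set = 0
            last_exit = t_idx
        elif s in b:
            if last_set == 0:
                durations.append((t_idx - last_exit) * traj.dt)
                directions.append(+1)
            last_set = 1
            last_exit = t_idx
    return TptSample(durations=np.array(durations), directions=np.array(directions, dtype=int))


def order_states_by_committor(model: TransitionModel, comm: CommittorVector):
    """Relabel states by ascending forward committor (source first, sink last).

    Returns (permutation, relabeled model); the permutation is a
    similarity transform, so the spectrum is unchanged."""
    key = comm.q_plus.copy()
    # force source strictly first and sink strictly last under ties
    key[comm.source] = -1.0
    key[comm.sink] = 2.0
    order = np.argsort(key, kind="stable")
    t_new = model.transition_mat[np.ix_(order, order)]
    c_new = model.count_mat[np.ix_(order, order)] if model.count_mat.shape == model.transition_mat.shape else model.count_mat
    relabeled = TransitionModel(
        lag_time=model.lag_time,
        count_mat=c_new,
        transition_mat=t_new,
        stationary=model.stationary[order],
        eigenvalues=model.eigenvalues,
        right_eigenvectors=model.right_eigenvectors[order, :],
        left_eigenvectors=model.left_eigenvectors[order, :],
        active_states=model.active_states[order] if len(model.active_states) == len(order) else model.active_states,
        trimmed_states=model.trimmed_states,
        reversible=model.reversible,
    )
    return order, relabeled
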