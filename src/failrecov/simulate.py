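"""Exact stochastic simulation of the three-process failure-recovery model.

Each node is in one of three states: ACTIVE (A), internally failed (X) or
externally failed (Y).  The continuous-time Markov chain is driven by

* spontaneous (internal) failure  A -> X at rate ``p``,
* induced (external) failure      A -> Y at rate ``r``, enabled only while
  the node sits in a *critically damaged neighborhood* (CDN): at most ``m``
  of its neighbors are active,
* recoveries X -> A at rate ``q`` and Y -> A at rate ``q'``.

Failed nodes never convert between X and Y and cannot fail again; recovery
is unconditional on the neighborhood.  The simulator is a rejection-free
Gillespie (kinetic Monte Carlo) implementation: per-node total exit rates
are kept in a binary sum tree so that each event costs O(log N), and after
an event only the flipped node and its neighbors are updated.  Identical
``(seed, inputs)`` give an identical event sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from numba import njit

from .networks import Network

__all__ = [
    "ACTIVE",
    "INT_FAILED",
    "EXT_FAILED",
    "ModelParams",
    "SimTrajectory",
    "is_cdn",
    "node_rates",
    "run_gillespie",
    "export_snapshot",
    "write_snapshot",
    "read_snapshot",
]

ACTIVE, INT_FAILED, EXT_FAILED = 0, 1, 2


@dataclass(frozen=True)
class ModelParams:
    """The five control parameters of the dynamics.

    ``p``: internal failure rate, ``r``: external (induced) failure rate,
    ``q``: internal recovery rate, ``q_prime``: external recovery rate,
    ``m``: CDN threshold (a neighborhood is critically damaged when the
    number of active neighbors is <= m).
    """

    p: float
    r: float
    q: float
    q_prime: float
    m: int

    def __post_init__(self) -> None:
        for name in ("p", "r", "q", "q_prime"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")
        if self.m < 0 or int(self.m) != self.m:
            raise ValueError("m must be a non-negative integer")


@dataclass
class SimTrajectory:
    """Sampled compartment fractions from one stochastic realization."""

    times: np.ndarray
    z: np.ndarray
    u_int: np.ndarray
    u_ext: np.ndarray
    seed: int
    params: ModelParams
    event_count: int
    final_states: np.ndarray
    snapshots: list = field(default_factory=list)  # list of (time, state vector)
    network: Optional[Network] = None

    @property
    def a(self) -> np.ndarray:
        """Total failed fraction, ``a = u_int + u_ext = 1 - z``."""
        return self.u_int + self.u_ext


def is_cdn(net: Network, states: np.ndarray, node: int, m: int) -> bool:
    """Whether ``node`` sits in a critically damaged neighborhood.

    True iff the number of ACTIVE neighbors is <= m; an isolated node is
    always in a CDN (0 active neighbors).
    """
    if not 0 <= node < net.n:
        raise KeyError(f"unknown node id {node}")
    indptr, indices = net.adjacency_csr()
    nbrs = indices[indptr[node] : indptr[node + 1]]
    return int(np.sum(states[nbrs] == ACTIVE)) <= m


def node_rates(
    net: Network, states: np.ndarray, params: ModelParams, node: int
) -> tuple[float, list[tuple[int, float]]]:
    """Total exit rate and event menu ``[(target_state, rate), ...]`` for a node."""
    s = states[node]
    if s == ACTIVE:
        menu = [(INT_FAILED, params.p)]
        if is_cdn(net, states, node, params.m):
            menu.append((EXT_FAILED, params.r))
    elif s == INT_FAILED:
        menu = [(ACTIVE, params.q)]
    elif s == EXT_FAILED:
        menu = [(ACTIVE, params.q_prime)]
    else:
        raise ValueError(f"invalid state {s}")
    menu = [(t, rate) for t, rate in menu if rate > 0]
    return sum(rate for _, rate in menu), menu


@njit(cache=True)
def _gillespie_core(
    indptr, indices, states, p, r, q, qp, m, t_max, sample_dt, seed, snap_times
):  # pragma: no cover - exercised through run_gillespie
    np.random.seed(seed)
    n = states.shape[0]

    act_nbrs = np.zeros(n, dtype=np.int64)
    for u in range(n):
        for j in range(indptr[u], indptr[u + 1]):
            if states[indices[j]] == 0:
                act_nbrs[u] += 1

    n_a = 0
    n_x = 0
    n_y = 0
    for u in range(n):
        if states[u] == 0:
            n_a += 1
        elif states[u] == 1:
            n_x += 1
        else:
            n_y += 1

    M = 1
    while M < n:
        M *= 2
    tree = np.zeros(2 * M, dtype=np.float64)
    for u in range(n):
        s = states[u]
        if s == 0:
            rate = p + (r if act_nbrs[u] <= m else 0.0)
        elif s == 1:
            rate = q
        else:
            rate = qp
        tree[M + u] = rate
    for i in range(M - 1, 0, -1):
        tree[i] = tree[2 * i] + tree[2 * i + 1]

    n_samples = int(math.floor(t_max / sample_dt + 1e-9)) + 1
    counts = np.empty((n_samples, 3), dtype=np.int64)
    n_snaps = snap_times.shape[0]
    snaps = np.zeros((n_snaps, n), dtype=np.int8)

    t = 0.0
    si = 0
    ei = 0
    events = 0
    while True:
        total = tree[1]
        if total > 1e-300:
            t_next = t - math.log(np.random.random()) / total
        else:
            t_next = math.inf
        # record grid samples / snapshots falling before the next event
        while si < n_samples and si * sample_dt <= min(t_next, t_max) + 1e-12:
            counts[si, 0] = n_a
            counts[si, 1] = n_x
            counts[si, 2] = n_y
            si += 1
        while ei < n_snaps and snap_times[ei] <= min(t_next, t_max) + 1e-12:
            for u in range(n):
                snaps[ei, u] = states[u]
            ei += 1
        if t_next > t_max:
            break
        t = t_next

        # select node proportionally to its total rate
        x = np.random.random() * total
        i = 1
        while i < M:
            l = 2 * i
            if x < tree[l]:
                i = l
            else:
                x -= tree[l]
                i = l + 1
        u = i - M

        s = states[u]
        if s == 0:
            in_cdn = act_nbrs[u] <= m
            # two competing clocks decide the failure type
            if in_cdn and np.random.random() * (p + r) >= p:
                states[u] = 2
                n_y += 1
            else:
                states[u] = 1
                n_x += 1
            n_a -= 1
            became_active = False
        else:
            if s == 1:
                n_x -= 1
            else:
                n_y -= 1
            states[u] = 0
            n_a += 1
            became_active = True

        # refresh the flipped node's rate
        s = states[u]
        if s == 0:
            rate = p + (r if act_nbrs[u] <= m else 0.0)
        elif s == 1:
            rate = q
        else:
            rate = qp
        i = M + u
        tree[i] = rate
        i >>= 1
        while i >= 1:
            tree[i] = tree[2 * i] + tree[2 * i + 1]
            i >>= 1

        # neighbors' active-neighbor counts (and CDN status) change
        delta = 1 if became_active else -1
        for j in range(indptr[u], indptr[u + 1]):
            v = indices[j]
            act_nbrs[v] += delta
            if states[v] == 0:
                rate = p + (r if act_nbrs[v] <= m else 0.0)
                i = M + v
                tree[i] = rate
                i >>= 1
                while i >= 1:
                    tree[i] = tree[2 * i] + tree[2 * i + 1]
                    i >>= 1
        events += 1

    return counts, snaps, events, states


def _resolve_init(
    net: Network,
    init: Union[str, float, np.ndarray],
    rng: np.random.Generator,
    init_failed_state: int = INT_FAILED,
) -> np.ndarray:
    if isinstance(init, str):
        if init == "all-active":
            return np.zeros(net.n, dtype=np.int8)
        if init == "all-failed":
            return np.full(net.n, init_failed_state, dtype=np.int8)
        raise ValueError(f"unknown init '{init}'")
    if np.isscalar(init):
        frac = float(init)
        if not 0 <= frac <= 1:
            raise ValueError("init fraction must be in [0, 1]")
        states = np.zeros(net.n, dtype=np.int8)
        k = int(round(frac * net.n))
        idx = rng.choice(net.n, size=k, replace=False)
        states[idx] = init_failed_state
        return states
    states = np.asarray(init, dtype=np.int8)
    if states.shape != (net.n,):
        raise ValueError(f"init state vector must have length {net.n}")
    if states.size and (states.min() < 0 or states.max() > 2):
        raise ValueError("init states must be in {0, 1, 2}")
    return states.copy()


def run_gillespie(
    net: Network,
    params: ModelParams,
    init: Union[str, float, np.ndarray] = "all-active",
    t_max: float = 100.0,
    sample_dt: float = 1.0,
    seed: int = 0,
    snapshot_times: Optional[Sequence[float]] = None,
    init_failed_state: int = INT_FAILED,
) -> SimTrajectory:
    """Run one exact realization of the failure-recovery chain.

    Parameters
    ----------
    net
        The substrate network.
    params
        Model rates and CDN threshold.
    init
        ``"all-active"``, ``"all-failed"``, a failed fraction in [0, 1]
        (failed nodes drawn uniformly, assigned ``init_failed_state``), or an
        explicit per-node state vector.
    t_max, sample_dt
        Simulation horizon and uniform sampling interval (piecewise-constant
        interpolation between events).
    seed
        Seeds both the initial-condition draw and the event sequence.
    snapshot_times
        Optional times at which the full state vector is recorded.

    Returns
    -------
    SimTrajectory
        Compartment fractions on the sample grid, the final state vector,
        any requested snapshots and the total event count.
    """
    if not (t_max > 0 and math.isfinite(t_max)):
        raise ValueError("t_max must be positive and finite")
    if not sample_dt > 0:
        raise ValueError("sample_dt must be positive")
    rng = np.random.default_rng(seed)
    states = _resolve_init(net, init, rng, init_failed_state)
    snap_times = np.asarray(
        sorted(snapshot_times) if snapshot_times is not None else [], dtype=np.float64
    )
    indptr, indices = net.adjacency_csr()
    counts, snaps, events, final = _gillespie_core(
        indptr,
        indices,
        states,
        float(params.p),
        float(params.r),
        float(params.q),
        float(params.q_prime),
        int(params.m),
        float(t_max),
        float(sample_dt),
        int(seed) % 2**32,
        snap_times,
    )
    n_samples = counts.shape[0]
    times = np.arange(n_samples) * sample_dt
    snapshots = [(float(t), snaps[i].copy()) for i, t in enumerate(snap_times)]
    return SimTrajectory(
        times=times,
        z=counts[:, 0] / net.n,
        u_int=counts[:, 1] / net.n,
        u_ext=counts[:, 2] / net.n,
        seed=seed,
        params=params,
        event_count=int(events),
        final_states=np.asarray(final, dtype=np.int8),
        snapshots=snapshots,
        network=net,
    )


def export_snapshot(traj: SimTrajectory, index: int) -> np.ndarray:
    """Return snapshot ``index`` as an L x L matrix of state codes {0, 1, 2}."""
    if not traj.snapshots:
        raise ValueError("trajectory carries no snapshots")
    net = traj.network
    if net is None or net.lattice_side is None or net.coords is None:
        raise ValueError("snapshot export needs a lattice-embedded network")
    _, states = traj.snapshots[index]
    L = net.lattice_side
    grid = np.zeros((L, L), dtype=np.int8)
    grid[net.coords[:, 0], net.coords[:, 1]] = states
    return grid


def write_snapshot(grid: np.ndarray, path) -> None:
    """Write a snapshot matrix as plain text, one lattice row per line."""
    np.savetxt(path, grid, fmt="%d")


def read_snapshot(path) -> np.ndarray:
    grid = np.loadtxt(path, dtype=np.int8)
    return np.atleast_2d(grid)
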