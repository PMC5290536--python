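"""Graph families for failure-recovery dynamics.

Three undirected, simple graph families are supported:

* periodic / open square lattices (the spatially embedded baseline),
* random regular graphs (the perfectly mixed counterpart),
* spatially embedded networks on a periodic lattice whose link lengths
  follow a truncated exponential (geometric) law ``P(l) ~ exp(-l/zeta)``.
  The characteristic link length ``zeta`` interpolates between the square
  lattice (``zeta -> 0``) and a random regular graph (``zeta -> inf``).

All generators are seeded and deterministic; edges are stored as a sorted
``(E, 2)`` integer array with ``u < v`` per row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "EmbeddedNetworkSpec",
    "make_square_lattice",
    "make_regular_random_graph",
    "make_embedded_network",
    "degree_distribution",
]


@dataclass
class Network:
    """Undirected simple graph with optional lattice embedding.

    Parameters
    ----------
    n
        Number of nodes; node ids are ``0 .. n-1``.
    edges
        ``(E, 2)`` integer array, each row an unordered pair stored with
        ``u < v``, rows sorted lexicographically.
    coords
        Optional ``(n, 2)`` integer lattice coordinates ``(i, j)``.
    lattice_side
        Side length ``L`` when the nodes sit on an ``L x L`` lattice.
    periodic
        Whether the lattice embedding wraps around.
    """

    n: int
    edges: np.ndarray
    coords: Optional[np.ndarray] = None
    lattice_side: Optional[int] = None
    periodic: bool = False
    _adj: Optional[tuple] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int64)
        if e.size == 0:
            e = e.reshape(0, 2)
        if e.ndim != 2 or e.shape[1] != 2:
            raise ValueError("edges must be an (E, 2) array")
        if e.size and (e.min() < 0 or e.max() >= self.n):
            raise ValueError("edge endpoint out of range")
        if np.any(e[:, 0] == e[:, 1]):
            raise ValueError("self-loop in edge list")
        e = np.sort(e, axis=1)
        e = e[np.lexsort((e[:, 1], e[:, 0]))]
        if e.shape[0] > 1 and np.any(np.all(np.diff(e, axis=0) == 0, axis=1)):
            raise ValueError("duplicate edge in edge list")
        self.edges = e
        if self.coords is not None:
            c = np.asarray(self.coords, dtype=np.int64)
            if c.shape != (self.n, 2):
                raise ValueError("coords must be (n, 2)")
            if self.lattice_side is not None:
                L = self.lattice_side
                if self.n != L * L:
                    raise ValueError("lattice_side inconsistent with node count")
                if c.min() < 0 or c.max() >= L:
                    raise ValueError("coordinates outside [0, L)^2")
                if len({(int(x), int(y)) for x, y in c}) != self.n:
                    raise ValueError("coordinates not unique")
            self.coords = c

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def degrees(self) -> np.ndarray:
        """Degree of every node."""
        return np.bincount(self.edges.ravel(), minlength=self.n)

    def adjacency_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Adjacency in CSR form ``(indptr, indices)`` for the simulator."""
        if self._adj is None:
            deg = self.degrees()
            indptr = np.zeros(self.n + 1, dtype=np.int64)
            np.cumsum(deg, out=indptr[1:])
            indices = np.empty(2 * self.n_edges, dtype=np.int64)
            fill = indptr[:-1].copy()
            for u, v in self.edges:
                indices[fill[u]] = v
                fill[u] += 1
                indices[fill[v]] = u
                fill[v] += 1
            self._adj = (indptr, indices)
        return self._adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges))
        return g


@dataclass(frozen=True)
class EmbeddedNetworkSpec:
    """Specification of a spatially embedded network on a periodic lattice."""

    lattice_side: int
    zeta: float
    target_degree: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_side < 3:
            raise ValueError("lattice_side must be >= 3")
        if not self.zeta > 0:
            raise ValueError("zeta must be > 0")
        if self.target_degree < 1:
            raise ValueError("target_degree must be >= 1")


def _from_networkx(g: nx.Graph, **kw) -> Network:
    edges = np.array([(u, v) for u, v in g.edges()], dtype=np.int64)
    return Network(n=g.number_of_nodes(), edges=edges, **kw)


def make_square_lattice(L: int, periodic: bool = True) -> Network:
    """``L x L`` square lattice with row-major node ids ``i*L + j``.

    The periodic lattice is 4-regular.  ``L < 3`` with ``periodic=True`` is
    rejected because wrapping would create duplicate edges.
    """
    if periodic and L < 3:
        raise ValueError("periodic lattice needs L >= 3 (L < 3 creates duplicate edges)")
    if not periodic and L < 2:
        raise ValueError("lattice needs L >= 2")
    g = nx.grid_2d_graph(L, L, periodic=periodic)
    mapping = {(i, j): i * L + j for i, j in g.nodes()}
    g = nx.relabel_nodes(g, mapping)
    coords = np.array([(i // L, i % L) for i in range(L * L)], dtype=np.int64)
    return _from_networkx(g, coords=coords, lattice_side=L, periodic=periodic)


def make_regular_random_graph(N: int, k: int, seed: int = 0) -> Network:
    """Simple k-regular random graph on ``N`` nodes (configuration model)."""
    if N * k % 2 != 0:
        raise ValueError("N*k must be even (odd stub count)")
    if k >= N:
        raise ValueError("k must be < N")
    g = nx.random_regular_graph(k, N, seed=int(seed))
    return _from_networkx(g)


def _offsets_by_length(L: int) -> dict[int, np.ndarray]:
    """Minimal-image lattice offsets grouped by rounded Euclidean distance."""
    half = L // 2
    groups: dict[int, list[tuple[int, int]]] = {}
    rng_d = range(-half, half + 1) if L % 2 else range(-half + 1, half + 1)
    for dx in rng_d:
        for dy in rng_d:
            if dx == 0 and dy == 0:
                continue
            l = int(round(math.hypot(dx, dy)))
            if 1 <= l <= half:
                groups.setdefault(l, []).append((dx, dy))
    return {l: np.array(v, dtype=np.int64) for l, v in sorted(groups.items())}


def make_embedded_network(spec: EmbeddedNetworkSpec) -> Network:
    """Embedded network with exponentially distributed link lengths.

    Nodes sit on a periodic ``L x L`` lattice; each carries ``target_degree``
    stubs.  Stubs are matched by drawing a link length ``l`` from the
    truncated geometric law ``P(l) ~ exp(-l/zeta)`` on ``{1, ..., L//2}``
    (rounded minimal-image Euclidean distance) and picking a partner with a
    free stub at that distance uniformly.  When no partner exists at the
    drawn length after a retry budget, the nearest feasible length is used;
    stubs that cannot be matched at all are dropped, so the achieved degree
    sequence may fall marginally short of exact regularity.
    """
    L, zeta, k = spec.lattice_side, spec.zeta, spec.target_degree
    rng = np.random.default_rng(spec.seed)
    n = L * L
    groups = _offsets_by_length(L)
    lengths = np.array(sorted(groups), dtype=np.int64)
    # geometric weights, normalised; exp underflows harmlessly for tiny zeta
    logw = -lengths / zeta
    w = np.exp(logw - logw.max())
    w /= w.sum()

    coords = np.array([(i // L, i % L) for i in range(n)], dtype=np.int64)
    free = np.full(n, k, dtype=np.int64)
    adj: list[set[int]] = [set() for _ in range(n)]
    edges: list[tuple[int, int]] = []

    def candidates(u: int, l: int) -> np.ndarray:
        offs = groups[l]
        xi, yi = coords[u]
        vs = ((xi + offs[:, 0]) % L) * L + (yi + offs[:, 1]) % L
        mask = (free[vs] > 0) & (vs != u)
        vs = vs[mask]
        if vs.size:
            vs = vs[[int(v) not in adj[u] for v in vs]]
        return vs

    def neighbors_at(u: int, l: int) -> np.ndarray:
        offs = groups[l]
        xi, yi = coords[u]
        return ((xi + offs[:, 0]) % L) * L + (yi + offs[:, 1]) % L

    def connect(u: int, v: int) -> None:
        adj[u].add(v)
        adj[v].add(u)
        free[u] -= 1
        free[v] -= 1

    # one queue entry per stub, consumed in random global order so that no
    # neighborhood is depleted prematurely; saturated neighborhoods are
    # repaired by an edge swap (break an edge of a saturated partner and
    # requeue the displaced stub) before falling back to a relaxed length
    queue = list(rng.permutation(np.repeat(np.arange(n), k)))
    retry_budget = 8
    max_iter = 10 * n * k
    it = 0
    while queue and it < max_iter:
        it += 1
        u = int(queue.pop())
        if free[u] <= 0:
            continue
        l0 = int(rng.choice(lengths, p=w))
        vs = candidates(u, l0)
        for _ in range(retry_budget - 1):
            if vs.size:
                break
            l0 = int(rng.choice(lengths, p=w))
            vs = candidates(u, l0)
        if vs.size:
            connect(u, int(vs[rng.integers(vs.size)]))
            continue
        # swap: steal a partner at the drawn length from one of its edges
        cand = neighbors_at(u, l0)
        cand = cand[cand != u]
        cand = np.array([v for v in cand if int(v) not in adj[u] and adj[int(v)]])
        if cand.size:
            v = int(cand[rng.integers(cand.size)])
            others = [x for x in adj[v] if x != u]
            if others:
                x = others[int(rng.integers(len(others)))]
                adj[v].discard(x)
                adj[x].discard(v)
                free[x] += 1
                free[v] += 1
                connect(u, v)
                queue.append(x)
                continue
        # relax to the nearest feasible length
        placed = False
        for l in sorted(lengths, key=lambda a: (abs(a - l0), a)):
            vs = candidates(u, int(l))
            if vs.size:
                connect(u, int(vs[rng.integers(vs.size)]))
                placed = True
                break
        if not placed:
            free[u] = 0  # unmatched stubs dropped

    for u in range(n):
        for v in adj[u]:
            if u < v:
                edges.append((u, v))

    net = Network(
        n=n,
        edges=np.array(edges, dtype=np.int64),
        coords=coords,
        lattice_side=L,
        periodic=True,
    )
    mean_deg = 2 * net.n_edges / n
    if abs(mean_deg - k) > 0.01 * k:
        raise RuntimeError(
            f"embedded construction achieved mean degree {mean_deg:.3f}, "
            f"more than 1% from target {k}"
        )
    return net


def degree_distribution(net: Network) -> dict[int, float]:
    """Empirical degree distribution ``f_k`` (sums to one)."""
    deg = net.degrees()
    ks, counts = np.unique(deg, return_counts=True)
    return {int(k): float(c) / net.n for k, c in zip(ks, counts)}


def link_lengths(net: Network) -> np.ndarray:
    """Rounded minimal-image Euclidean length of every edge (lattice nets only)."""
    if net.coords is None or net.lattice_side is None:
        raise ValueError("network has no lattice embedding")
    L = net.lattice_side
    d = np.abs(net.coords[net.edges[:, 0]] - net.coords[net.edges[:, 1]])
    if net.periodic:
        d = np.minimum(d, L - d)
    return np.round(np.hypot(d[:, 0], d[:, 1])).astype(np.int64)
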