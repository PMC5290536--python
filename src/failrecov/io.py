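"""Configuration, edge-list I/O and packaged test fixtures.

The config dialect is flat YAML with documented defaults; edge lists are
plain text with one ``u<TAB>v`` pair per line (0-based ids, ``u < v``,
sorted) and an optional ``id<TAB>x<TAB>y`` coordinates sidecar.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import networks
from .networks import EmbeddedNetworkSpec, Network
from .simulate import ModelParams

__all__ = [
    "RunConfig",
    "load_config",
    "dump_config",
    "read_edgelist",
    "write_edgelist",
    "make_fixture",
    "FIXTURE_NAMES",
]

_EXPERIMENTS = ("simulate", "meanfield", "hysteresis", "phase-diagram", "cusp")
_NETWORK_KINDS = ("lattice", "rrg", "embedded", "edgelist")


@dataclass
class RunConfig:
    """Validated flat configuration for one experiment run."""

    experiment: str = "simulate"
    # model parameters
    p: float = 0.1
    r: float = 0.95
    q: float = 1.0
    q_prime: float = 0.1
    m: int = 1
    # network source (exactly one of lattice/rrg/embedded/edgelist)
    network: str = "lattice"
    L: int = 50
    N: int = 2500
    k: int = 4
    zeta: float = 1.0
    periodic: bool = True
    edgelist: Optional[str] = None
    # run options
    t_max: float = 100.0
    sample_dt: float = 1.0
    init_active_fraction: float = 1.0
    seed: int = 0
    out_dir: str = "."

    def model_params(self) -> ModelParams:
        return ModelParams(p=self.p, r=self.r, q=self.q, q_prime=self.q_prime, m=self.m)

    def build_network(self) -> Network:
        if self.network == "lattice":
            return networks.make_square_lattice(self.L, periodic=self.periodic)
        if self.network == "rrg":
            return networks.make_regular_random_graph(self.N, self.k, seed=self.seed)
        if self.network == "embedded":
            return networks.make_embedded_network(
                EmbeddedNetworkSpec(self.L, self.zeta, self.k, self.seed)
            )
        if self.network == "edgelist":
            if self.edgelist is None:
                raise ValueError("network 'edgelist' requires key 'edgelist'")
            return read_edgelist(self.edgelist)
        raise ValueError(f"unknown network kind '{self.network}'")

    def validate(self) -> "RunConfig":
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(
                f"experiment must be one of {_EXPERIMENTS}, got '{self.experiment}'"
            )
        if self.network not in _NETWORK_KINDS:
            raise ValueError(
                f"network must be one of {_NETWORK_KINDS}, got '{self.network}'"
            )
        for name in ("p", "r", "q", "q_prime"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate '{name}' must be >= 0")
        if self.m < 0:
            raise ValueError("'m' must be >= 0")
        if self.t_max <= 0 or self.sample_dt <= 0:
            raise ValueError("'t_max' and 'sample_dt' must be > 0")
        if not 0 <= self.init_active_fraction <= 1:
            raise ValueError("'init_active_fraction' must be in [0, 1]")
        if self.network == "edgelist":
            if self.edgelist is None or not Path(self.edgelist).exists():
                raise ValueError(f"edgelist path does not exist: {self.edgelist}")
        return self


def load_config(path) -> RunConfig:
    """Load and validate a flat YAML config; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of flat keys")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    return RunConfig(**raw).validate()


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True, default_flow_style=False)
    )


def write_edgelist(net: Network, path) -> None:
    """Write sorted ``u<TAB>v`` lines plus a coordinates sidecar if embedded."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in net.edges:
            fh.write(f"{u}\t{v}\n")
    if net.coords is not None:
        side = path.with_suffix(path.suffix + ".coords")
        with side.open("w") as fh:
            for i, (x, y) in enumerate(net.coords):
                fh.write(f"{i}\t{x}\t{y}\n")


def read_edgelist(path) -> Network:
    """Read an edge-list file (with optional ``.coords`` sidecar)."""
    path = Path(path)
    edges = []
    seen = set()
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: malformed line {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer node id in {line!r}")
            if u == v:
                raise ValueError(f"{path}:{ln}: self-loop {u}-{v}")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise ValueError(f"{path}:{ln}: duplicate edge {u}-{v}")
            seen.add(key)
            edges.append(key)
    if not edges:
        raise ValueError(f"{path}: no edges")
    n = max(max(e) for e in edges) + 1
    coords = None
    lattice_side = None
    side = path.with_suffix(path.suffix + ".coords")
    if side.exists():
        coords = np.zeros((n, 2), dtype=np.int64)
        with side.open() as fh:
            for line in fh:
                if line.strip():
                    i, x, y = map(int, line.split())
                    coords[i] = (x, y)
        L = int(round(np.sqrt(n)))
        if L * L == n:
            lattice_side = L
    return Network(
        n=n, edges=np.array(edges, dtype=np.int64), coords=coords, lattice_side=lattice_side
    )


FIXTURE_NAMES = (
    "single-node",
    "three-cycle",
    "lattice3x3",
    "rrg-small",
    "switching-point",
    "limit-cycle",
)


@dataclass
class Fixture:
    name: str
    network: Optional[Network]
    params: ModelParams
    expected: dict = field(default_factory=dict)


def make_fixture(name: str) -> Fixture:
    """Small networks with parameter sets and analytically known expectations.

    ``single-node``: isolated node with all rates 1 — the three-state chain
    A <-> X, A <-> Y has stationary active probability
    ``1 / (1 + p/q + r/q')`` = 1/3.  ``switching-point`` and ``limit-cycle`` are the
    phase-switching and limit-cycle operating points.
    """
    if name == "single-node":
        params = ModelParams(p=1.0, r=1.0, q=1.0, q_prime=1.0, m=0)
        net = Network(n=1, edges=np.zeros((0, 2), dtype=np.int64))
        s = params.p / params.q + params.r / params.q_prime
        return Fixture(
            name,
            net,
            params,
            expected={
                "active_fraction": 1.0 / (1.0 + s),
                "u_int": (params.p / params.q) / (1.0 + s),
                "u_ext": (params.r / params.q_prime) / (1.0 + s),
            },
        )
    if name == "three-cycle":
        params = ModelParams(p=0.5, r=1.5, q=1.0, q_prime=0.5, m=1)
        net = Network(n=3, edges=np.array([[0, 1], [0, 2], [1, 2]]))
        return Fixture(name, net, params, expected={"oracle": "master-equation"})
    if name == "lattice3x3":
        net = networks.make_square_lattice(3, periodic=True)
        params = ModelParams(p=0.2, r=1.0, q=1.0, q_prime=0.5, m=1)
        return Fixture(
            name, net, params, expected={"n_nodes": 9, "n_edges": 18, "degree": 4}
        )
    if name == "rrg-small":
        net = networks.make_regular_random_graph(20, 4, seed=7)
        params = ModelParams(p=0.2, r=1.0, q=1.0, q_prime=0.5, m=1)
        return Fixture(name, net, params, expected={"degree": 4})
    if name == "switching-point":
        net = networks.make_square_lattice(50, periodic=True)
        params = ModelParams(p=0.1065, r=0.95, q=1.0, q_prime=0.1, m=1)
        return Fixture(name, net, params, expected={"phase_switching": True})
    if name == "limit-cycle":
        # limit-cycle operating point: effective rates at the cusp, q' > q
        q, qp = 0.01, 1.0
        params = ModelParams(p=(19 / 81) * q, r=(3125 / 1296) * qp, q=q, q_prime=qp, m=1)
        return Fixture(
            name,
            None,
            params,
            expected={
                "k": 4,
                "p_over_q": 19 / 81,
                "r_over_qprime": 3125 / 1296,
                "cusp_a": 2 / 5,
                "oscillatory": True,
            },
        )
    raise KeyError(f"unknown fixture '{name}' (choose from {FIXTURE_NAMES})")
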