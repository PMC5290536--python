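"""Exact master-equation solution of the failure-recovery chain on tiny graphs.

Enumerates all ``3**N`` joint states of an N-node network, assembles the
generator of the continuous-time Markov chain directly from the process
definition, and solves for the stationary distribution with a sparse linear
solve.  This is an independent route to the stationary compartment
fractions used to validate the event-driven simulator; it is only feasible
for N up to about 10.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .networks import Network
from .simulate import ModelParams

__all__ = ["stationary_distribution", "stationary_fractions"]

_MAX_NODES = 12


def _decode_states(n: int) -> np.ndarray:
    """(3**n, n) matrix of per-node states for every joint state index."""
    s = np.arange(3**n, dtype=np.int64)
    return (s[:, None] // 3 ** np.arange(n, dtype=np.int64)[None, :]) % 3


def stationary_distribution(net: Network, params: ModelParams) -> np.ndarray:
    """Stationary probability vector over the ``3**N`` joint states."""
    n = net.n
    if n > _MAX_NODES:
        raise ValueError(f"master equation limited to N <= {_MAX_NODES}, got {n}")
    digits = _decode_states(n)  # (S, n)
    S = digits.shape[0]
    active = digits == 0

    adj = np.zeros((n, n), dtype=np.int64)
    for u, v in net.edges:
        adj[u, v] = adj[v, u] = 1
    act_nbrs = active.astype(np.int64) @ adj  # (S, n) active-neighbor counts

    pow3 = 3 ** np.arange(n, dtype=np.int64)
    rows, cols, rates = [], [], []

    def add(src_mask: np.ndarray, node: int, delta: np.ndarray, rate: float) -> None:
        if rate <= 0:
            return
        src = np.nonzero(src_mask)[0]
        rows.append(src + delta)
        cols.append(src)
        rates.append(np.full(src.size, rate))

    for i in range(n):
        a_i = active[:, i]
        cdn_i = act_nbrs[:, i] <= params.m
        add(a_i, i, pow3[i], params.p)            # A -> X
        add(a_i & cdn_i, i, 2 * pow3[i], params.r)  # A -> Y (CDN only)
        add(digits[:, i] == 1, i, -pow3[i], params.q)       # X -> A
        add(digits[:, i] == 2, i, -2 * pow3[i], params.q_prime)  # Y -> A

    if not rows:
        # no process active: any distribution is stationary; report the
        # uniform one for definiteness
        return np.full(S, 1.0 / S)

    row = np.concatenate(rows)
    col = np.concatenate(cols)
    val = np.concatenate(rates)
    W = sp.coo_matrix((val, (row, col)), shape=(S, S)).tocsr()
    out = np.asarray(W.sum(axis=0), dtype=np.float64).ravel()
    Q = W - sp.diags(out)  # columns sum to zero; Q pi = 0

    if S <= 1000:
        # dense null-space solve for tiny chains
        A = Q.toarray()
        A[-1, :] = 1.0
        b = np.zeros(S)
        b[-1] = 1.0
        pi = np.linalg.lstsq(A, b, rcond=None)[0]
    else:
        # stationary vector as the Perron eigenvector of the uniformized
        # transition matrix P = I + Q / Lambda (avoids LU fill-in)
        lam = out.max() * 1.05 + 1e-12
        P = sp.eye(S, format="csr") + Q.tocsr() / lam
        vals, vecs = spla.eigs(P, k=1, which="LM", v0=np.full(S, 1.0 / S), tol=1e-13)
        pi = np.real(vecs[:, 0])
        if pi.sum() < 0:
            pi = -pi
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = np.abs(Q @ pi).max()
    if resid > 1e-8:
        raise RuntimeError(f"stationary solve did not converge (residual {resid:.2e})")
    return pi


def stationary_fractions(net: Network, params: ModelParams) -> tuple[float, float, float]:
    """Exact stationary expectations of ``(z, u_int, u_ext)``."""
    pi = stationary_distribution(net, params)
    digits = _decode_states(net.n)
    z = float(pi @ np.mean(digits == 0, axis=1))
    u_int = float(pi @ np.mean(digits == 1, axis=1))
    u_ext = float(pi @ np.mean(digits == 2, axis=1))
    return z, u_int, u_ext
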