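"""Mean-field theory of the failure-recovery model.

Under perfect mixing the compartment fractions obey the coupled rate
equations

    du_int/dt = p (1 - a) - q  u_int
    du_ext/dt = r (1 - a) E(a) - q' u_ext,        a = u_int + u_ext,

where ``E(a)`` is the probability that a node sits in a critically damaged
neighborhood (at most ``m`` active neighbors) when each neighbor is failed
independently with probability ``a``:

    E(a) = sum_k f_k  sum_{j=0}^{min(m,k)} C(k, j) (1-a)^j a^(k-j),

with ``f_k`` the degree distribution.  Stationary states solve

    F(a) = (p/q)(1 - a) + (r/q') (1 - a) E(a) - a = 0,

which depends only on the effective rates ``p/q`` and ``r/q'``.  For
``m < k`` the map ``a -> (1-a)E(a)`` is S-shaped and F can have three roots:
two stable and one unstable state coexist inside a wedge of the
``(r/q', p/q)`` plane bounded by two saddle-node (spinodal) curves which
merge at a cusp point where ``F = F' = F'' = 0``.  All of these objects are
computed here; everything is polynomial in ``a`` for finite-support f_k, so
exact rational results are available for the cusp of k-regular graphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import sympy
from numpy.polynomial import Polynomial
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import comb

from .simulate import ModelParams

__all__ = [
    "MeanFieldState",
    "StationaryBranch",
    "Spinodals",
    "MeanFieldTrajectory",
    "cdn_probability",
    "cdn_polynomial",
    "rhs",
    "integrate",
    "stationary_states",
    "spinodals",
    "cusp_point",
    "cusp_point_exact",
    "classify_phase",
    "hysteresis_area",
]

FkLike = Union[int, dict]


def _as_fk(f_k: FkLike) -> dict[int, float]:
    if isinstance(f_k, (int, np.integer)):
        return {int(f_k): 1.0}
    total = sum(f_k.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"degree distribution sums to {total}, not 1")
    return {int(k): float(v) for k, v in f_k.items()}


@dataclass(frozen=True)
class MeanFieldState:
    u_int: float
    u_ext: float

    def __post_init__(self) -> None:
        a = self.u_int + self.u_ext
        if self.u_int < -1e-12 or self.u_ext < -1e-12 or a > 1 + 1e-12:
            raise ValueError("state outside the simplex {u_int, u_ext >= 0, a <= 1}")

    @property
    def a(self) -> float:
        return self.u_int + self.u_ext


@dataclass
class StationaryBranch:
    """Stationary solutions at one point of the (p/q, r/q') plane."""

    p_over_q: float
    r_over_qprime: float
    roots: list  # entries: (a, u_int, u_ext, label or None)

    @property
    def a_values(self) -> list[float]:
        return [r[0] for r in self.roots]

    @property
    def labels(self) -> list:
        return [r[3] for r in self.roots]


@dataclass
class Spinodals:
    """The two saddle-node curves and their cusp meeting point.

    ``upper`` and ``lower`` are ``(n, 3)`` arrays of
    ``(r_over_qprime, p_over_q, a)`` triples; the upper curve carries the
    larger p/q at a given r/q'.  Curves exist only for r/q' beyond the cusp.
    """

    upper: np.ndarray
    lower: np.ndarray
    cusp: tuple  # (a, p_over_q, r_over_qprime)


@dataclass
class MeanFieldTrajectory:
    times: np.ndarray
    u_int: np.ndarray
    u_ext: np.ndarray

    @property
    def a(self) -> np.ndarray:
        return self.u_int + self.u_ext

    @property
    def z(self) -> np.ndarray:
        return 1.0 - self.a


def cdn_polynomial(f_k: FkLike, m: int) -> Polynomial:
    """E(a) as a polynomial in the failed fraction a."""
    fk = _as_fk(f_k)
    one_minus_a = Polynomial([1.0, -1.0])
    a_poly = Polynomial([0.0, 1.0])
    E = Polynomial([0.0])
    for k, fkv in fk.items():
        Ek = Polynomial([0.0])
        for j in range(0, min(m, k) + 1):
            Ek += comb(k, j, exact=True) * one_minus_a**j * a_poly ** (k - j)
        E += fkv * Ek
    return E


def cdn_probability(a, f_k: FkLike, m: int):
    """Probability E(a) of a critically damaged neighborhood at failed fraction a."""
    arr = np.asarray(a, dtype=float)
    if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
        raise ValueError("a must lie in [0, 1]")
    E = cdn_polynomial(f_k, m)
    out = np.clip(E(arr), 0.0, 1.0)
    return float(out) if np.isscalar(a) else out


def _G_poly(f_k: FkLike, m: int) -> Polynomial:
    """G(a) = (1 - a) E(a), the active-and-CDN probability."""
    return Polynomial([1.0, -1.0]) * cdn_polynomial(f_k, m)


def rhs(
    state: MeanFieldState, params: ModelParams, f_k: FkLike
) -> tuple[float, float]:
    """Time derivatives (du_int/dt, du_ext/dt) of the rate equations."""
    a = state.a
    E = cdn_probability(min(max(a, 0.0), 1.0), f_k, params.m)
    d_int = params.p * (1 - a) - params.q * state.u_int
    d_ext = params.r * (1 - a) * E - params.q_prime * state.u_ext
    return d_int, d_ext


def integrate(
    params: ModelParams,
    f_k: FkLike,
    init: MeanFieldState = MeanFieldState(0.0, 0.0),
    t_max: float = 100.0,
    dt_out: float = 0.1,
) -> MeanFieldTrajectory:
    """Integrate the rate equations with an adaptive stiff-capable solver."""
    if not t_max > 0:
        raise ValueError("t_max must be positive")
    E = cdn_polynomial(f_k, params.m)

    def f(_t, y):
        a = min(max(y[0] + y[1], 0.0), 1.0)
        return [
            params.p * (1 - a) - params.q * y[0],
            params.r * (1 - a) * E(a) - params.q_prime * y[1],
        ]

    t_eval = np.arange(0.0, t_max + dt_out / 2, dt_out)
    sol = solve_ivp(
        f,
        (0.0, t_max),
        [init.u_int, init.u_ext],
        method="LSODA",
        t_eval=t_eval,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    u_int = np.clip(sol.y[0], 0.0, 1.0)
    u_ext = np.clip(sol.y[1], 0.0, 1.0)
    return MeanFieldTrajectory(times=sol.t, u_int=u_int, u_ext=u_ext)


def _stationary_poly(p_over_q: float, r_over_qprime: float, f_k: FkLike, m: int) -> Polynomial:
    one_minus_a = Polynomial([1.0, -1.0])
    return (
        p_over_q * one_minus_a
        + r_over_qprime * _G_poly(f_k, m)
        - Polynomial([0.0, 1.0])
    )


def _jacobian(a: float, p: float, q: float, r: float, qp: float, Gd: Polynomial) -> np.ndarray:
    g = Gd(a)
    return np.array([[-p - q, -p], [r * g, r * g - qp]])


def stationary_states(
    p_over_q: float,
    r_over_qprime: float,
    f_k: FkLike,
    m: int,
    params_abs: Optional[tuple[float, float]] = None,
    n_scan: int = 2000,
) -> StationaryBranch:
    """All stationary failed fractions a* in [0, 1], with optional stability.

    Roots of F are located by a sign-change scan on a uniform grid followed
    by bisection and a Newton polish.  Stability labels require the absolute
    recovery rates ``params_abs = (q, q')``; with ratios alone the labels are
    omitted (the 2D Jacobian depends on q and q' separately).
    """
    if p_over_q < 0 or r_over_qprime < 0:
        raise ValueError("effective rates must be >= 0")
    F = _stationary_poly(p_over_q, r_over_qprime, f_k, m)
    Fd = F.deriv()
    grid = np.linspace(0.0, 1.0, n_scan + 1)
    vals = F(grid)
    roots: list[float] = []
    for i in range(n_scan):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(F, grid[i], grid[i + 1], xtol=1e-14))
    if vals[-1] == 0.0:
        roots.append(1.0)
    # Newton polish and dedupe
    polished = []
    for a in roots:
        d = Fd(a)
        if abs(d) > 1e-8:
            a = a - F(a) / d
        a = min(max(a, 0.0), 1.0)
        if not any(abs(a - b) < 1e-8 for b in polished):
            polished.append(a)
    polished.sort()

    p_abs = q_abs = r_abs = qp_abs = None
    Gd = _G_poly(f_k, m).deriv()
    if params_abs is not None:
        q_abs, qp_abs = params_abs
        p_abs, r_abs = p_over_q * q_abs, r_over_qprime * qp_abs

    out = []
    for a in polished:
        u_int = p_over_q * (1 - a)
        u_ext = a - u_int
        label = None
        if params_abs is not None:
            J = _jacobian(a, p_abs, q_abs, r_abs, qp_abs, Gd)
            ev = np.linalg.eigvals(J)
            re = ev.real.max()
            if re < 0:
                label = "stable"
            elif np.any(np.abs(ev.imag) > 1e-12):
                label = "oscillatory-unstable"
            else:
                label = "unstable"
        out.append((float(a), float(u_int), float(u_ext), label))
    return StationaryBranch(p_over_q, r_over_qprime, out)


def _spinodal_parametric(a: np.ndarray, G: Polynomial) -> tuple[np.ndarray, np.ndarray]:
    """(r/q', p/q) on the saddle-node locus parametrized by the failed fraction.

    F = 0 and F' = 0 are linear in (p/q, r/q'); solving gives
    r/q' = 1 / [G'(a)(1-a) + G(a)] and p/q = G'(a) (r/q') - 1.
    """
    Gd = G.deriv()
    D = Gd(a) * (1 - a) + G(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(D > 0, 1.0 / D, np.nan)
        P = Gd(a) * R - 1.0
    return R, P


def cusp_point(f_k: FkLike, m: int) -> tuple[float, float, float]:
    """Numeric cusp point ``(a*, p/q, r/q')`` where F = F' = F'' = 0.

    Since F'' = (r/q') G''(a), the cusp failed fraction is a root of G'' in
    (0, 1); the two effective rates then follow from the linear system
    F = F' = 0.  Raises if the degree distribution admits no bistability
    (e.g. m at least the maximum degree, where E is identically one).
    """
    fk = _as_fk(f_k)
    if m >= max(fk):
        raise ValueError("no induced bistability: m >= maximum degree")
    G = _G_poly(fk, m)
    G2 = G.deriv(2)
    cands = [
        float(z.real)
        for z in G2.roots()
        if abs(z.imag) < 1e-10 and 1e-9 < z.real < 1 - 1e-9
    ]
    best = None
    for a in sorted(cands):
        # polish on G'' for full precision
        try:
            lo, hi = max(a - 1e-3, 1e-9), min(a + 1e-3, 1 - 1e-9)
            if G2(lo) * G2(hi) < 0:
                a = brentq(G2, lo, hi, xtol=1e-15)
        except ValueError:
            pass
        R, P = _spinodal_parametric(np.array([a]), G)
        R, P = float(R[0]), float(P[0])
        if np.isfinite(R) and R > 0 and P > 0:
            F = _stationary_poly(P, R, fk, m)
            if max(abs(F(a)), abs(F.deriv()(a)), abs(F.deriv(2)(a))) < 1e-10:
                best = (a, P, R)
                break
    if best is None:
        raise ValueError("no admissible cusp root of G'' in (0, 1)")
    return best


def cusp_point_exact(k: int, m: int):
    """Exact (rational/algebraic) cusp point for a k-regular graph.

    Returns sympy expressions ``(a*, p/q, r/q')`` solving F = F' = F'' = 0.
    For k = 4, m = 1 these are 2/5, 19/81 and 3125/1296.
    """
    if m >= k:
        raise ValueError("no induced bistability: m >= degree")
    a = sympy.Symbol("a")
    E = sum(
        sympy.binomial(k, j) * (1 - a) ** j * a ** (k - j) for j in range(0, m + 1)
    )
    G = sympy.expand((1 - a) * E)
    G2 = sympy.diff(G, a, 2)
    Gd = sympy.diff(G, a)
    for root in sympy.solve(G2, a):
        if not root.is_real:
            continue
        if not (0 < root < 1):
            continue
        D = sympy.simplify((Gd * (1 - a) + G).subs(a, root))
        if D == 0:
            continue
        R = sympy.nsimplify(1 / D)
        P = sympy.simplify(Gd.subs(a, root) * R - 1)
        if P > 0 and R > 0:
            return sympy.nsimplify(root), sympy.nsimplify(P), sympy.nsimplify(R)
    raise ValueError("no admissible cusp root in (0, 1)")


def spinodals(f_k: FkLike, m: int, a_grid: Optional[np.ndarray] = None) -> Spinodals:
    """The two saddle-node curves in the (r/q', p/q) plane and their cusp.

    Parametrized by the stationary failed fraction a; only points with both
    effective rates non-negative are returned.  The branch with a below the
    cusp value and the branch above it form the two curves; they are labelled
    upper/lower by their p/q ordering at common r/q'.
    """
    a_c, p_c, r_c = cusp_point(f_k, m)
    G = _G_poly(f_k, m)
    if a_grid is None:
        a_grid = np.linspace(1e-6, 1 - 1e-6, 4001)
    a_grid = np.asarray(a_grid, dtype=float)

    def branch(mask: np.ndarray) -> np.ndarray:
        aa = a_grid[mask]
        R, P = _spinodal_parametric(aa, G)
        ok = np.isfinite(R) & np.isfinite(P) & (R >= 0) & (P >= 0)
        out = np.column_stack([R[ok], P[ok], aa[ok]])
        return out[np.argsort(out[:, 0])]

    b_lo_a = branch(a_grid < a_c)  # a below cusp
    b_hi_a = branch(a_grid > a_c)  # a above cusp

    # decide which branch carries the larger p/q at a common r/q'
    upper, lower = b_hi_a, b_lo_a
    r_probe = r_c * 1.5
    pu = np.interp(r_probe, b_hi_a[:, 0], b_hi_a[:, 1]) if len(b_hi_a) else -np.inf
    pl = np.interp(r_probe, b_lo_a[:, 0], b_lo_a[:, 1]) if len(b_lo_a) else -np.inf
    if pl > pu:
        upper, lower = b_lo_a, b_hi_a
    return Spinodals(upper=upper, lower=lower, cusp=(a_c, p_c, r_c))


def hysteresis_area(
    spin: Spinodals,
    window: tuple[tuple[float, float], tuple[float, float]],
    n_grid: int = 2000,
) -> float:
    """Area enclosed by the spinodal curves inside a window.

    ``window = ((r_min, r_max), (p_min, p_max))`` in the (r/q', p/q) plane.
    The gap between the upper and lower p/q curves is clipped to the window
    and integrated over r/q' with the trapezoid rule; the result is the size
    of the bistable (hysteresis) region visible in that window.
    """
    (r_min, r_max), (p_min, p_max) = window
    if r_max <= r_min or p_max <= p_min:
        return 0.0
    r_c = spin.cusp[2]
    lo = max(r_min, r_c)
    if lo >= r_max or len(spin.upper) == 0 or len(spin.lower) == 0:
        return 0.0
    R = np.linspace(lo, r_max, n_grid)
    Pu = np.interp(R, spin.upper[:, 0], spin.upper[:, 1])
    Pl = np.interp(R, spin.lower[:, 0], spin.lower[:, 1])
    Pu = np.clip(Pu, p_min, p_max)
    Pl = np.clip(Pl, p_min, p_max)
    gap = np.clip(Pu - Pl, 0.0, None)
    return float(np.trapezoid(gap, R))


def classify_phase(
    p_over_q: float,
    r_over_qprime: float,
    q: float,
    q_prime: float,
    f_k: FkLike,
    m: int,
    t_max: Optional[float] = None,
) -> str:
    """Phase label at one parameter point: LOW, HIGH, BISTABLE or OSCILLATORY.

    BISTABLE requires three stationary states with two stable; a unique
    unstable stationary state triggers an ODE integration and Fourier check
    for a periodic attractor (possible only for q' > q); otherwise the label
    is LOW or HIGH according to the stationary failed fraction.
    """
    from .analysis import oscillation_detect

    br = stationary_states(p_over_q, r_over_qprime, f_k, m, params_abs=(q, q_prime))
    stable = [r for r in br.roots if r[3] == "stable"]
    if len(br.roots) == 3 and len(stable) == 2:
        return "BISTABLE"
    if len(stable) == 0 and br.roots:
        # unique unstable fixed point: look for a limit cycle
        if t_max is None:
            t_max = 100.0 / min(q, q_prime)
        params = ModelParams(
            p=p_over_q * q, r=r_over_qprime * q_prime, q=q, q_prime=q_prime, m=m
        )
        a0, u0, e0, _ = br.roots[0]
        init = MeanFieldState(min(u0 + 0.05, 1.0 - e0), e0)
        traj = integrate(params, f_k, init=init, t_max=t_max, dt_out=t_max / 4096)
        periodic, _, _ = oscillation_detect(traj.times, traj.z)
        if periodic:
            return "OSCILLATORY"
    a_star = stable[0][0] if stable else br.roots[0][0]
    return "HIGH" if a_star > 0.5 else "LOW"
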