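"""Phase-switching statistics, hysteresis protocols and oscillation detection.

Inside the bistable wedge of the phase diagram a finite system flips
stochastically between the low- and high-activity states; this module
quantifies that switching (dwell times, switch counts, bimodality of the
activity histogram), runs the up/down parameter sweeps that expose
hysteresis, detects limit cycles in the mean-field flow by Fourier
analysis of z(t), and builds simulation-based phase diagrams from a
two-initial-condition protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .meanfield import MeanFieldState, integrate
from .networks import Network
from . import simulate
from .simulate import ModelParams, SimTrajectory, run_gillespie

__all__ = [
    "SwitchingStats",
    "HysteresisResult",
    "PhaseDiagramProtocol",
    "detect_switching",
    "hysteresis_loop",
    "oscillation_detect",
    "no_closed_orbits_check",
    "simulated_phase_diagram",
]


@dataclass
class SwitchingStats:
    threshold_low: float
    threshold_high: float
    dwell_times: list
    n_switches: int
    bimodality: float


@dataclass
class HysteresisResult:
    p_values: np.ndarray
    forward_z: np.ndarray
    backward_z: np.ndarray
    forward_se: np.ndarray
    backward_se: np.ndarray

    @property
    def gap(self) -> float:
        return float(np.max(np.abs(self.forward_z - self.backward_z)))

    @property
    def gap_se(self) -> float:
        i = int(np.argmax(np.abs(self.forward_z - self.backward_z)))
        return float(math.hypot(self.forward_se[i], self.backward_se[i]))


def detect_switching(
    traj: SimTrajectory, band: tuple[float, float] = (0.3, 0.7)
) -> SwitchingStats:
    """Assign high/low activity phases by hysteresis-band crossing of z(t).

    The system enters the HIGH phase when z exceeds ``band[1]`` and the LOW
    phase when z drops below ``band[0]``; crossings of the band interior do
    not count.  Dwell times are the durations between consecutive phase
    entries.  The bimodality coefficient ``(skew^2 + 1) / kurtosis`` of the
    z histogram exceeds 5/9 for strongly bimodal samples.
    """
    low, high = band
    if not low < high:
        raise ValueError("band must satisfy low < high")
    z = np.asarray(traj.z)
    t = np.asarray(traj.times)
    if z.size < 10:
        raise ValueError("trajectory too short (< 10 samples)")
    phase = 0  # 0 = undecided, 1 = high, -1 = low
    switch_times = []
    for ti, zi in zip(t, z):
        if zi > high and phase != 1:
            if phase == -1:
                switch_times.append(ti)
            phase = 1
            if len(switch_times) == 0:
                switch_times.append(ti)
        elif zi < low and phase != -1:
            if phase == 1:
                switch_times.append(ti)
            phase = -1
            if len(switch_times) == 0:
                switch_times.append(ti)
    n_switches = max(len(switch_times) - 1, 0)
    dwell = list(np.diff(switch_times)) if len(switch_times) > 1 else []
    if z.std() < 1e-12:
        bimod = float("nan")
    else:
        kurt = stats.kurtosis(z, fisher=False)
        bimod = float((stats.skew(z) ** 2 + 1) / kurt) if kurt > 0 else float("nan")
    return SwitchingStats(low, high, dwell, n_switches, bimod)


def _batch_mean_se(x: np.ndarray, n_batches: int = 10) -> tuple[float, float]:
    """Mean and batch-means standard error for a correlated series."""
    n = x.size
    if n < n_batches:
        return float(np.mean(x)), float(np.std(x) / math.sqrt(max(n, 1)))
    nb = (n // n_batches) * n_batches
    means = x[:nb].reshape(n_batches, -1).mean(axis=1)
    return float(np.mean(means)), float(np.std(means, ddof=1) / math.sqrt(n_batches))


def hysteresis_loop(
    net: Network,
    params_base: ModelParams,
    p_grid: Sequence[float],
    t_relax: float = 50.0,
    t_measure: float = 50.0,
    seed: int = 0,
    sample_dt: float = 0.5,
) -> HysteresisResult:
    """Sweep the internal failure rate p up and then back down.

    Each step continues from the final microscopic state of the previous
    one, discards ``t_relax`` and averages z over ``t_measure``; the forward
    sweep starts from all-active, the backward sweep continues from the
    forward endpoint.  A nonzero gap between the two branches signals
    hysteresis (a discontinuous transition).
    """
    p_grid = np.asarray(p_grid, dtype=float)
    if np.any(np.diff(p_grid) <= 0):
        raise ValueError("p_grid must be sorted ascending")
    if t_relax <= 0 or t_measure <= 0:
        raise ValueError("t_relax and t_measure must be positive")

    def sweep(ps: np.ndarray, state, seed0: int):
        zs, ses = [], []
        for i, p in enumerate(ps):
            params = replace(params_base, p=float(p))
            traj = run_gillespie(
                net,
                params,
                init=state,
                t_max=t_relax + t_measure,
                sample_dt=sample_dt,
                seed=seed0 + i,
            )
            keep = traj.times >= t_relax
            mu, se = _batch_mean_se(traj.z[keep])
            zs.append(mu)
            ses.append(se)
            state = traj.final_states
        return np.array(zs), np.array(ses), state

    fwd_z, fwd_se, state = sweep(p_grid, "all-active", seed)
    bwd_z, bwd_se, _ = sweep(p_grid[::-1], state, seed + len(p_grid))
    return HysteresisResult(
        p_values=p_grid,
        forward_z=fwd_z,
        backward_z=bwd_z[::-1],
        forward_se=fwd_se,
        backward_se=bwd_se[::-1],
    )


def oscillation_detect(
    times: np.ndarray, z_series: np.ndarray, peak_factor: float = 10.0
) -> tuple[bool, float, float]:
    """Detect a sustained periodic component in z(t) by Fourier analysis.

    The last half of the uniformly sampled series is linearly detrended and
    transformed; the signal is called periodic when the dominant non-zero
    frequency carries at least ``peak_factor`` times the median spectral
    power AND the oscillation is sustained: its peak-to-peak amplitude in
    the final quarter must not have decayed below half of that in the third
    quarter (this rejects damped spirals into a stable focus).  Returns
    ``(is_periodic, dominant_frequency, peak_ratio)``.
    """
    t = np.asarray(times, dtype=float)
    z = np.asarray(z_series, dtype=float)
    if t.size < 64:
        raise ValueError("need at least 64 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("sampling must be uniform")
    half = t.size // 2
    zz = z[half:]
    tt = t[half:]
    # linear detrend removes the DC component and slow drift
    coef = np.polyfit(tt, zz, 1)
    resid = zz - np.polyval(coef, tt)
    if resid.std() < 1e-9:  # numerically flat after detrending
        return False, 0.0, 0.0
    power = np.abs(np.fft.rfft(resid)) ** 2
    freqs = np.fft.rfftfreq(resid.size, d=float(dt[0]))
    power = power[1:]
    freqs = freqs[1:]
    med = np.median(power)
    i = int(np.argmax(power))
    if med <= 0 or power[i] == 0:
        return False, 0.0, 0.0
    ratio = float(power[i] / med)
    q = resid.size // 2
    ptp3, ptp4 = np.ptp(resid[:q]), np.ptp(resid[q:])
    sustained = ptp4 > 1e-6 and ptp4 >= 0.5 * ptp3
    return ratio >= peak_factor and sustained, float(freqs[i]), ratio


@dataclass
class OrbitReport:
    points: list  # (p, r)
    periodic_flags: list
    converged_flags: list

    @property
    def any_periodic(self) -> bool:
        return any(self.periodic_flags)

    @property
    def all_converged(self) -> bool:
        return all(self.converged_flags)


def no_closed_orbits_check(
    f_k,
    m: int,
    q: float,
    q_prime: float,
    parameter_sample: Sequence[tuple[float, float]],
    t_max: Optional[float] = None,
    n_inits: int = 5,
    seed: int = 0,
) -> OrbitReport:
    """Numerically probe the mean-field flow for closed orbits.

    For each (p, r) pair, the rate equations are integrated from random
    initial states; a point is flagged periodic if the Fourier detector
    fires on z(t), and converged if the late-time derivative norm drops
    below 1e-8.  For q > q' no flags are expected (the flow admits a
    Lyapunov function and hence no closed orbits); for q' > q limit cycles
    can occur.
    """
    rng = np.random.default_rng(seed)
    if t_max is None:
        t_max = 100.0 / min(q, q_prime)
    pts, per, conv = [], [], []
    for p, r in parameter_sample:
        params = ModelParams(p=p, r=r, q=q, q_prime=q_prime, m=m)
        flagged = False
        settled = True
        for _ in range(n_inits):
            u = rng.random(2)
            if u.sum() > 1:
                u = 1 - u  # uniform on the simplex
            traj = integrate(
                params,
                f_k,
                init=MeanFieldState(float(u[0]), float(u[1])),
                t_max=t_max,
                dt_out=t_max / 2048,
            )
            ok, _, _ = oscillation_detect(traj.times, traj.z)
            flagged = flagged or ok
            from .meanfield import rhs

            d = rhs(
                MeanFieldState(float(traj.u_int[-1]), float(traj.u_ext[-1])),
                params,
                f_k,
            )
            settled = settled and math.hypot(*d) < 1e-8
        pts.append((p, r))
        per.append(flagged)
        conv.append(settled)
    return OrbitReport(points=pts, periodic_flags=per, converged_flags=conv)


@dataclass
class PhaseDiagramProtocol:
    """Protocol settings for simulation-based phase classification."""

    q: float = 1.0
    q_prime: float = 0.1
    m: int = 1
    t_relax: float = 60.0
    t_measure: float = 40.0
    sample_dt: float = 0.5
    min_gap: float = 0.2
    seed: int = 0
    # the high-failure branch is dominated by externally failed (Y) nodes,
    # so the all-failed initial condition seeds that type
    init_failed_state: int = simulate.EXT_FAILED


@dataclass
class PhaseDiagramResult:
    p_over_q: np.ndarray
    r_over_qprime: np.ndarray
    labels: np.ndarray  # (len(p), len(r)) of {LOW, HIGH, BISTABLE}
    z_from_active: np.ndarray
    z_from_failed: np.ndarray

    def count(self, label: str) -> int:
        return int(np.sum(self.labels == label))


def simulated_phase_diagram(
    net: Network,
    p_over_q_grid: Sequence[float],
    r_over_qprime_grid: Sequence[float],
    protocol: PhaseDiagramProtocol = PhaseDiagramProtocol(),
) -> PhaseDiagramResult:
    """Classify each grid point from simulations with two initial conditions.

    Runs from all-active and from all-failed; the point is BISTABLE when the
    two stationary ``<z>`` differ by more than 3 pooled standard errors and
    by at least ``protocol.min_gap`` (metastable lifetimes far exceed any
    feasible run, so the initial condition selects the branch); otherwise
    LOW/HIGH according to the mean failed fraction.
    """
    ps = np.asarray(p_over_q_grid, dtype=float)
    rs = np.asarray(r_over_qprime_grid, dtype=float)
    labels = np.empty((ps.size, rs.size), dtype=object)
    z_a = np.empty((ps.size, rs.size))
    z_f = np.empty((ps.size, rs.size))
    t_total = protocol.t_relax + protocol.t_measure
    for i, pq in enumerate(ps):
        for j, rq in enumerate(rs):
            params = ModelParams(
                p=pq * protocol.q,
                r=rq * protocol.q_prime,
                q=protocol.q,
                q_prime=protocol.q_prime,
                m=protocol.m,
            )
            mus, ses = [], []
            for which, init in enumerate(("all-active", "all-failed")):
                traj = run_gillespie(
                    net,
                    params,
                    init=init,
                    t_max=t_total,
                    sample_dt=protocol.sample_dt,
                    seed=protocol.seed + 7919 * (2 * (i * rs.size + j) + which),
                    init_failed_state=protocol.init_failed_state,
                )
                keep = traj.times >= protocol.t_relax
                mu, se = _batch_mean_se(traj.z[keep])
                mus.append(mu)
                ses.append(se)
            z_a[i, j], z_f[i, j] = mus
            diff = abs(mus[0] - mus[1])
            pooled = math.hypot(*ses)
            if diff > max(3 * pooled, protocol.min_gap):
                labels[i, j] = "BISTABLE"
            else:
                mean_a = 1 - 0.5 * (mus[0] + mus[1])
                labels[i, j] = "HIGH" if mean_a > 0.5 else "LOW"
    return PhaseDiagramResult(ps, rs, labels, z_a, z_f)
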