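# Methods

## Model definition

Nodes are active (A), internally failed (X) or externally failed (Y).
Transitions are Markovian with rates

| transition | rate | condition |
|---|---|---|
| A → X | `p` | always (spontaneous, field-like failure) |
| A → Y | `r` | only in a critically damaged neighborhood (CDN) |
| X → A | `q` | always |
| Y → A | `q′` | always |

A node is in a CDN when at most `m` of its neighbors are active; an
isolated node is always in a CDN. Failed nodes cannot fail again and X/Y
never interconvert; recovery is unconditional on the neighborhood. An
active node in a CDN therefore carries two competing exponential clocks
(total exit rate `p + r`), and which clock fires decides the failure type.
The threshold rule makes the induced channel a complex contagion: for a
degree-4 node with `m = 1`, at least three neighbors must be down before
damage can propagate.

## Exact stochastic simulation

The simulator is a rejection-free direct-method Gillespie implementation.
Per-node total exit rates are stored in the leaves of a binary sum tree;
waiting times are exponential in the root total, the firing node is found
by descending the tree (O(log N)), and after each event only the flipped
node and its neighbors are updated (their active-neighbor counts, CDN
status and rates). Compartment counts are maintained incrementally and
sampled on a uniform grid with piecewise-constant interpolation between
events; optional full-state snapshots are recorded at requested times.
The core loop is numba-compiled and uses numba's own seeded Mersenne
Twister, so identical `(seed, inputs)` reproduce the exact event
sequence. Throughput is roughly 5×10⁶ events/s on one core.

Initial conditions: `"all-active"`, `"all-failed"`, a failed fraction, or
an explicit state vector. Failed initial nodes default to type X; the
`init_failed_state` flag selects Y instead. This matters physically: the
low-activity phase is Y-dominated (X nodes recover at the fast rate `q`),
so probes of that phase's metastability must start from Y-failed states.

## Master-equation oracle

For networks with N ≤ 12 nodes the full generator of the `3^N`-state
chain is assembled directly from the table above and its stationary
distribution is computed independently of the simulator: densely (null
space) for small state spaces, otherwise as the Perron eigenvector of the
uniformized transition matrix `P = I + Q/Λ` via ARPACK (a direct sparse
LU of the generator is impractical — single-digit fill-in per column but
expander-like structure). Residual `‖Qπ‖∞ < 1e−8` is enforced. On the
3×3 periodic lattice (19 683 states) this takes ~0.2 s and pins the
simulator's long-run averages to three Monte-Carlo standard errors.

## Mean-field theory

With perfect mixing, `E(a) = Σ_k f_k Σ_{j≤min(m,k)} C(k,j)(1−a)^j a^(k−j)`
is the CDN probability at failed fraction `a` and the rate equations are
those in the README. All objects are polynomial in `a` for finite-support
degree distributions, which the implementation exploits throughout
(`numpy.polynomial` arithmetic; a brute-force polynomial-root oracle
backs the tests).

* **Stationary states** — roots of `F(a)` located by a sign-change scan on
  a 2000-point grid, bisection (`brentq`, xtol 1e−14) and one Newton
  polish; duplicates within 1e−8 are merged. Tangent (even-multiplicity)
  roots on the spinodal itself are inherently missed by a sign scan; the
  spinodal curves are computed parametrically instead (below), so nothing
  downstream depends on them. Stability comes from the eigenvalues of the
  2×2 Jacobian and needs the absolute rates `(q, q′)`; with ratios alone
  labels are omitted rather than guessed.
* **Spinodals** — on the saddle-node locus, `F = F′ = 0` are linear in
  `(p/q, r/q′)`, giving the closed parametrization
  `r/q′ = 1/[G′(a)(1−a) + G(a)]`, `p/q = G′(a)(r/q′) − 1` with
  `G(a) = (1−a)E(a)`. The denominator is maximal at the cusp, so each
  side of the cusp value of `a` is a monotone branch; branches are
  labelled upper/lower by their `p/q` order at a common `r/q′`.
* **Cusp point** — `F″ = (r/q′)G″(a)`, so the cusp failed fraction is a
  root of `G″` in (0, 1). The numeric path polishes the polynomial root
  (residuals < 1e−12); an exact path builds the same equations in sympy
  with rational arithmetic, giving `a* = 2/5`, `p/q = 19/81`,
  `r/q′ = 3125/1296` for `k = 4, m = 1`. `m ≥ k` makes `E ≡ 1` and is
  rejected ("no induced bistability").
* **ODE integration** — `scipy.solve_ivp` with LSODA, rtol 1e−8,
  atol 1e−10 (the flow is stiff near saddle-nodes when `q′ ≪ q`).
* **Hysteresis area** — the gap between the two spinodal `p/q` curves,
  clipped to a window, integrated over `r/q′` with the trapezoid rule.

Mean-field accuracy: on a 4-regular random graph with N = 10⁴ the
low-density stationary state agrees with the simulator to < 0.005; in the
high-density regime neighbor correlations in the CDN indicator bias the
mean field by up to ~0.03 in `a` for k = 4 (the perfect-mixing assumption
is the binding approximation, not system size). The agreement test
therefore sits at a low-density monostable point with tolerance 0.02.

## Oscillation detection

A trajectory is declared periodic when, on the last half of a uniformly
sampled series after linear detrending, the dominant non-zero Fourier
peak carries ≥ 10× the median spectral power *and* the oscillation is
sustained: the peak-to-peak amplitude of the final quarter must be at
least half that of the third quarter and above 1e−6. The sustained
condition rejects damped spirals into a stable focus, which otherwise
produce spectrally concentrated transients. Limit cycles exist only for
`q′ > q`; the package checks the converse numerically
(`no_closed_orbits_check`) by integrating from random simplex points and
verifying convergence (late-time derivative norm < 1e−8), since the
closed-form Lyapunov construction fixes `β = 1`, `α = (q − q′)/p` and is
positive only when `q > q′`.

## Switching, hysteresis and phase-diagram protocols

* **Switching** — phases are assigned by hysteresis-band crossing of
  `z(t)` with default band (0.3, 0.7) (the two phases sit near z ≈ 0.82
  and z ≈ 0.15, so the band is uncritical); dwell times are the durations
  between phase entries. Bimodality uses the coefficient
  `(skew² + 1)/kurtosis`, which exceeds 5/9 for strongly bimodal samples.
* **Hysteresis loops** — `p` is swept up then down at fixed `(r, q, q′, m)`;
  each step continues from the previous microscopic state, discards
  `t_relax` and averages `z` over `t_measure` (batch-means standard
  errors). A *persistent* gap between the branches signals a
  discontinuous transition. A continuous but steep transition also
  produces a finite-time lag gap; the two are separated by slowing the
  protocol — lag gaps shrink towards zero, true hysteresis gaps survive.
  At N = 64², slowing t_relax = t_measure from 100 to 900 collapses the
  lattice gap at r = 0.7 from ≈ 0.34 to ≈ 0.02 while the random-graph gap
  only moves from ≈ 0.64 to ≈ 0.60.
* **Simulated phase diagrams** — each `(p/q, r/q′)` cell is run from
  all-active and from all-Y-failed; the cell is bistable when the two
  `⟨z⟩` differ by more than both 3 pooled standard errors and a minimum
  gap of 0.2. The two-initial-condition protocol replaces switching
  observation because metastable lifetimes (exponential in N) dwarf any
  feasible horizon. `t_relax = 300` is chosen so that the transient
  escape of the unstable branch on lattice-like topologies (measured
  escape times ≤ 150 at N = 50²) has resolved, leaving only genuine
  bistability.

## Embedded networks

Nodes sit on a periodic L×L lattice; each carries `target_degree` stubs.
Link lengths are drawn from the truncated geometric law
`P(l) ∝ exp(−l/ζ)` on `{1, …, ⌊L/2⌋}`, where length is the rounded
minimal-image Euclidean distance (an isotropic choice; note the diagonal
offsets round to length 1). Stubs are consumed in a global random order;
a partner with a free stub at the drawn length is chosen uniformly. When
a neighborhood is saturated, an edge swap steals a partner (breaking one
of its edges and requeueing the displaced stub) before falling back to
the nearest feasible length; unmatchable stubs are dropped, and a mean
degree within 1% of the target is enforced. The swap repair makes the
ζ → 0 limit exact (100% length-1 links at ζ = 0.05, L = 50) and the
length histogram at ζ = 10 consistent with the target law (χ² p ≈ 0.6),
while keeping the construction seeded and deterministic.

## Study conditions and problem sizes

Simulation scales follow the scaled study conditions: the 3×3 lattice for
the exact oracle; 50×50 lattices for switching and embedded-network phase
diagrams; 64² nodes for hysteresis loops; a 10⁴-node random regular graph
for the mean-field agreement check. The switching run at the operating
point `p = 0.1065, r = 0.95, q = 1, q′ = 0.1, m = 1` uses a horizon of
4×10⁶ time units: measured phase lifetimes there are ~5×10⁵ (low phase)
and ~1–2×10⁶ (high phase), so this horizon typically captures two or
more spontaneous switches. Phase-diagram grids use
`p/q ∈ [0.02, 0.14]` (7 values) × `r/q′ ∈ {2, 4, 6, 8, 10}`, spanning the
wedge from below the cusp (`r/q′ ≈ 2.41`) upward.

## Known limitations

* The mean field is quantitatively biased (~0.03 in `a`) at high density
  for small degrees; it is an upper-level description, not an oracle —
  the master equation plays that role at small N.
* The location of the lattice's switching window is extremely narrow
  (width ~1% in `p`) and sensitive to boundary conditions: with periodic
  boundaries the balance point of the two phase lifetimes at N = 50² sits
  at `p ≈ 0.1065–0.108`; with open boundaries it shifts down by ~3%
  (boundary nodes reach the CDN condition more easily).
* Switching times grow exponentially with N, so switching statistics are
  only accessible for small systems; large systems inside the wedge are
  effectively selected by their initial condition.
* The embedded-network construction attempts exact k-regularity but may
  drop a vanishing fraction of stubs on adversarial geometries; the
  achieved degree sequence is always available from the returned graph.
* Cluster-size/nucleation statistics and critical-exponent estimation are
  out of scope; snapshots are exported for qualitative inspection only.
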