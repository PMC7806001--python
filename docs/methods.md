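# Methods

This note records the model conventions, the numerical choices, and the
design decisions behind `growsim`, in the order a reader needs them to
interpret (or distrust) a simulation.

## State representation and frames

The organ is a discretized centerline of `N` segments of arc-length `ds`,
clamped at the base. The state consists solely of the two natural-frame
curvature components `(kappa1, kappa2)` per segment; frames and Cartesian
positions are *derived* quantities, reconstructed on demand. The natural
(Bishop) frame is used instead of Frenet–Serret because the Frenet normal
is undefined on a straight organ — precisely the initial condition of
every run. Where the Frenet angle ϕ (and hence torsion τ) is requested at
κ = 0 it is reported as NaN rather than an arbitrary value; τ of the
first defined segment in a contiguous run, which has no defined
predecessor, is reported as 0. ϕ is unwrapped along arc-length before
differencing so τ carries no spurious ±2π jumps.

Conventions that the model leaves open and we fix:

* The initial organ is vertical with T̂ = ẑ, m̂₁ = x̂, m̂₂ = ŷ (any fixed
  orthonormal pair is admissible; this one makes the planar scenarios live
  in the x–z plane).
* Frames are attached per segment, piecewise constant on
  `[n ds, (n+1) ds)`; positions are the `N + 1` segment endpoints
  `r(n) = base + Σ_{k<n} T̂(k) ds`. Attaching frames to midpoints instead
  would differ at O(ds).
* Frame propagation uses the exact rotation `R = exp(U ds)` of the
  skew-symmetric Darboux generator (Rodrigues closed form, with series
  fallback below angle 1e-8), so orthonormality is preserved by
  construction; the cumulative product along the organ is evaluated as a
  prefix-product scan, algebraically identical to the sequential product.

## Growth and the curvature update

Elongation at uniform rate `Edot` is confined to the apical growth zone of
length `Lgz`; the induced material velocity at a segment is
`v(n) = (Lgz − depth(n)) · Edot` clipped at zero, where `depth` is the
distance from the segment's apical end to the tip (so the tip segment
moves at exactly `Lgz·Edot`). The curvature update is the explicit scheme

    kappa_i(n, m+1) = kappa_i(n, m)
        + dt [ (Edot/R) Delta_i(n, m) − v(n) (kappa_i(n) − kappa_i(n−1)) / ds ],

a backward arc-length difference, which is the stable upwind choice since
the growth flow always runs base-to-tip. The base row is held at zero
(clamped). One segment is appended at the tip per step, copying its
predecessor's curvature — equivalent to initializing the incoming segment
with zero curvature, zero response, and tip velocity one step early, but
simpler. This forces the step-size relation `ds = Lgz · Edot · dt`, which
is validated at configuration time and never silently repaired.

Two deliberate choices deserve emphasis:

* **The source prefactor `Edot/R` is constant along the organ**, while the
  convective velocity vanishes below the growth zone. Under the
  alternative reading — zeroing the source where elongation is zero —
  mature tissue freezes, and the distant-stimulus run saturates at
  κ_max ≈ 1.1 instead of λ₀/γ = 10, because material transits the growth
  zone in ~(1/Edot)·ln(Lgz/ds) ≈ 46 time units while curvature needs
  T_c = R/(Edot γ) = 100 to converge. The constant-prefactor scheme lets
  the near-base region, held at right angles by the clamp, converge to the
  steady maximal curvature; it is the form whose steady state reproduces
  the analytic κ_max = λ/γ, and the one implemented here.
* **Time stepping is first-order explicit**, exactly the discretization
  above; no higher-order integrator is substituted, to keep the scheme
  directly comparable with the discrete update as stated. Stability
  requires `dt · (Edot/R) · γ_effective < 2` for the proprioceptive
  relaxation and the CFL number `v·dt/ds ≤ 1` (equal to 1 at the tip by
  the step-size relation); blow-ups are detected (non-finite curvature)
  and abort with a diagnostic rather than propagate.

## Stimuli, sensitivities, and scenario composition

A stimulus is a vector field `I(r) n̂(r)` — constant (distant source),
radial from a point, or radial from a line. The organ senses only the
projection perpendicular to its tangent, `I⊥ = |I| sin θ`, mapped to a
gain by a sensitivity law: constant, Weber–Fechner `a + b log(I/I₀)`, or
Stevens `a·I^b`. The raw response vector is `−λ(I⊥) n̂⊥` (zero when the
signal is tangential, since there is then no directional information); the
*scenario builders* own the attract/repel sign, so each published
composition formula is implemented exactly once. Attractive scenarios use
a unit-magnitude field with a linear (Stevens exponent 1) sensitivity and
sign −1, which reproduces e.g. `Δ⃗ = λ₀n̂ − γκN̂` for the distant case
term for term on the cross-section.

Proprioception is implemented directly in natural components as
`−γ·(kappa1, kappa2)`, never evaluating the possibly-undefined Frenet
normal (the term vanishes identically at κ = 0 regardless).

Apical sensing evaluates the response once at the tip and transports its
cross-sectional *components* `(λ⃗·m̂₁(L), λ⃗·m̂₂(L))` to every local
frame. The transport rule is a convention (the model only states that the
apex response is rotated to the local frame); component transport is the
choice that reduces exactly to local sensing on a straight organ and feeds
the curvature update in the quantities it actually consumes.

Point sources raise a degenerate-source error when queried closer than
1e-11 length units; positions exactly on a line stimulus get a zero radial
response (no directional information). Spatially varying magnitudes (e.g.
a diffusive concentration around a point source) are supported through an
optional radial profile; the default is constant.

## Parameters

All quantities are dimensionless model units. Defaults:

| parameter | symbol | default | meaning |
|---|---|---|---|
| `R` | R | 0.1 | organ radius; sets the lever arm of differential growth |
| `gamma` | γ | 0.01 | proprioceptive gain (length units, so γκ is dimensionless) |
| `lambda0` | λ₀ | 0.1 | primary tropic sensitivity → B = 10 |
| `lambda1` | λ₁ | 0.05 | secondary sensitivity (line/superposition) → B = 5 |
| `Lgz` | L_gz | 1.0 | growth-zone length |
| `L0` | L₀ | 1.0 | initial organ length (straight, vertical) |
| `growth_rate` | Ė | 0.1 | uniform elongation rate in the growth zone |
| `dt` | dt | 0.1 | time step |
| `ds` | ds | 0.01 | segment length, = L_gz·Ė·dt (hard constraint) |
| `omega` | ω | 0.2/dt | circumnutation angular rate, period 2π/ω ≈ 31 steps |

Derived scales: convergence length L_c = γ/λ, convergence time
T_c = R/(Ė γ), arrival time T_v = R/(Ė L_gz λ), balance number
B = λL_gz/γ = L_gz/L_c = T_c/T_v = κ_max·L_gz. With the defaults
κ_max·R = 1, the edge of the low-curvature regime (κR ≤ 1) the
linearized curvature dynamics assume.

The steady-state stopping rule (off by default; fixed horizons are the
default) declares convergence when `max_n |κ(m) − κ(m−1)|/dt < 1e-6` for
50 consecutive steps. At the defaults this triggers after ~11.7k steps
with κ_max within 1e-5 of λ₀/γ. The "arrival time" diagnostic is
operationalized as the first zero crossing of the signed tip-to-stimulus
angle (linearly interpolated between steps) — a convention, since "first
alignment" admits no unique discrete definition.

The 2D planar oracle integrates Dκ/Dt = (Ė/R)(λ sin θ − γκ) with
∂θ/∂s = −κ and θ(0) = π/2 on the same grid and stepping, sharing only
scalar arithmetic with the 3D code. The orientation (sign of ∂θ/∂s) is
fixed so θ decreases as the organ bends toward the stimulus, making the
oracle's κ match the 3D run's κ₁ > 0; the equivalence test pins this to
< 1e-8 over 500 steps. The accretive-growth comparison model
(∂κ/∂t = λ e^{−η(t−s)} sin θ, no material derivative, no proprioception)
is provided for qualitative comparison only.

## Optimal control module

The tip-steering module is deliberately standalone and 2D: a fixed-length
organ (growth neglected), parameterized by the tangent angle θ(s)
relative to the stimulus. The vector-form dynamics dT̂(s)/dt = s·u⃗(t) do
not preserve |T̂| under naive Euler stepping, so the integrator works in
θ-form — θ(s) ← θ(s) − dt·s·β·sin θ(L) — which is exactly the regime the
zero-cost optimal family selects (the cost ∫(T̂(L)·u⃗)² dt is identically
zero for u⃗ ∥ T̂⊥, to the last bit, since T̂·T̂⊥ cancels exactly in
floating point). The mixed-derivative form ∂ₜ∂ₛθ = −β sin θ(L) is also
provided and agrees with the θ-form integrator exactly on the node grid.
The gain β has no canonical value; β = 1 is the convention that
identifies the two formulations, and the module's guarantees (Lyapunov
decrease of |T̂(L) − n̂|, no oscillation about the stimulus, admissibility
n̂·u⃗ ≥ 0) are checked property-wise since there is no numerical
reference experiment.

## Problem sizes used in tests and the acceptance script

The acceptance script runs the distant-stimulus scenario with the default
parameters to the steady-state criterion (~11.7k steps, organ of ~12.7k
segments, about a minute), plus the two instantaneous balance-number
evaluations. The test suite uses shorter horizons (200–4000 steps) chosen
so each property is exercised well past its transient: planarity and
frame integrity over 1000 steps, oracle equivalence over 500, the
circumnutation period measured over ~10 revolutions.

## Known limitations

* No elasticity: no forces, torques, stretch or shear; self-intersection
  is permitted and not detected (the organ grows through itself).
* No branching, no collision, no occlusion or self-shadowing of stimuli.
* The twining scenario with the default coplanar geometry stays planar
  (the organ–line configuration is mirror-symmetric); genuinely helical
  twining requires a symmetry-breaking term such as superposed
  circumnutation.
* Explicit first-order stepping ties accuracy to the printed scheme;
  halving dt requires halving ds (the step-size relation), not an
  independent refinement.
* Chemical-gradient stimuli are supported only through their gradient
  direction field; what magnitude an organ actually senses for such
  stimuli is left open as a user-supplied sensitivity/profile.
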