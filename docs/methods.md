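# Methods

This note documents the model, the numerical choices, and the validation
benchmarks of `cvdom`, including the places where the design was genuinely
open and what the package chose.

## Transport model and discretization

The solver integrates the 2D time-dependent radiative transfer equation over
uniform rectangular cells (control volumes) and a constant-weight ordinate
set on the unit circle.  Directions are genuinely planar — M unit vectors
(ξ_m, η_m) at angles (m + ½)·2π/M, weights w_m = 2π/M — because the flux
divergence uses only the two in-plane cosines.  The half-step angular offset
keeps every ordinate strictly inside a sign quadrant, so the four upwind
sweep orderings are well defined and every ordinate has exact mirror
partners across both axes (required by the specular boundary closure).

For ordinate m, the cell update is the closed form

    I_P = [A f_x + B f_y + ΔxΔy (μs Σ_m' w_m' p_mm' I_m' + history + S)]
          / [ΔxΔy·ct + A + B + ΔxΔy (μa + μs)],

with A = Δy|ξ_m|/α, B = Δx|η_m|/α and upstream *face* radiances f_x, f_y.
Downstream faces follow from the interpolation closure
f_down = (I_P − (1−α) f_up)/α and are handed to the next cell along the
sweep.  The face bookkeeping matters: substituting upstream cell-center
values for the faces (a tempting shortcut) makes the effective attenuation
α·μ instead of μ for α ≠ 1 — a pure absorber then decays at half rate under
diamond interpolation.  With faces tracked properly, α = ½ attenuates per
cell by the Padé factor (1 − τ/2)/(1 + τ/2), second-order accurate in the
cell optical depth τ.

Time stepping is the implicit three-level stencil
∂I/∂t ≈ (3I^{n+1} − 4I^n + I^{n−1})/2Δt with coefficient n_m/(cΔt) per unit
volume (dimensional consistency with the Δy·ξ and ΔxΔy·μ terms requires the
cell-area factor on the time term).  The first step, which has no I^{n−1},
uses backward Euler; the scheme "forgets" this startup within a few steps
(a transient energy overshoot of ≤ 4/3 decays geometrically — the familiar
BDF2 startup artifact).  Within each step the scattering source is lagged
and iterated, with SOR blending I ← (1−ρ)I_k + ρI_{k+1} (ρ = 1.1), until
the per-element relative change max |ΔI| / max(|I|, ε_abs) falls below tol.
The floor ε_abs = 1e−300 exists only to guard division by zero on dark
cells; keeping it far below any physical radiance keeps the metric
scale-invariant in the source amplitude, which is what makes doubling the
source double every output *bit-exactly*.

The steady driver solves the identical equations with the time-derivative
terms dropped.  This is the exact fixed point of the marching scheme (the
3 − 4 + 1 stencil cancels at stationarity), so "march to equilibrium" and
"iterate the steady equations" agree; the transient→steady benchmark
verifies that end to end, and a `run_steady(problem, dt=...)` option still
performs the literal march.

Quadrant sweeps run in a fixed order, each re-applying its upstream
boundary closure with the newest outgoing faces (Gauss–Seidel coupling);
the converged result does not depend on the order.

### Phase-matrix discretization

The Henyey–Greenstein kernel with the standard 3/2 exponent is restricted
to the plane.  Discretizing it by *point sampling* at the ordinate-pair
angles fails once the forward peak (angular width ≈ 1−g) is narrower than
the ordinate spacing 2π/M: at g = 0.9, M = 32 the column renormalization
needed to conserve energy is a factor ≈ 0.26, and the resulting transport
misallocates escaping power between the sides by ~16% against a
continuous-angle Monte Carlo reference.  The package therefore builds the
phase matrix from *bin averages*: entry (m, m′) carries the kernel's exact
probability mass over the 2π/M bin centered on the discrete deflection
angle, divided by w.  Columns then sum to 1 up to quadrature rounding (a
final exact renormalization is still applied), the renormalization factor
stays at unity for all |g| ≤ 0.95 and M ≥ 16, and the solver agrees with
the Monte Carlo oracle to ~3% under the conditions above.  Point sampling
remains available as `phase_matrix(..., method="point")`.

A consequence worth knowing: the planar restriction of the 3/2-exponent
kernel is more forward-peaked than its 3D parent.  Its mean deflection
cosine is not g but (for example) 0.9816 at g = 0.9, computed by
quadrature (`inplane_hg_mean_cosine`).  Both the solver and the Monte Carlo
sampler use this same planar kernel — consistency between the two routes is
what makes the cross-validation meaningful — so the *effective* in-plane
anisotropy of a run exceeds the nominal g.  The Monte Carlo moment test
accordingly checks the sampled mean against the kernel's own quadrature
mean, not against g.

### Interpolation parameter α

α = ½ (diamond) is the accuracy default for CW steady runs.  Two regimes
need the stabilized upwind variant α = 1 and use it in the validation
suite:

- **Collimated-beam discontinuities.**  Diamond's face closure
  f_down = 2I_P − f_up is undamped across steep gradients; around a pure
  collimated beam it produces an oscillating ±tail that propagates to the
  lateral boundaries and contaminates even row-integrated quantities at the
  percent level.  The Beer–Lambert benchmark therefore runs upwind, where
  the attenuation error is the benign first-order 1/(1+τ) ≈ e^{−τ+τ²/2}
  (≈1% at τ = 0.02).
- **Pulse transients at Δt = 1e−13 s.**  The implicit time coefficient
  adds ΔxΔy·n/(cΔt) to the removal term, making every cell ~35 effective
  optical depths thick per step at Δx = 0.05 cm; diamond faces then flip
  sign cell-to-cell with no damping and the detector series is garbage at
  early times.  Upwind keeps the transient positive and physically shaped.

Negative radiances under diamond are *reported* (`n_negative`,
`min_radiance` on results), never clipped.

## Sources, detectors, units

All lengths in cm, time in s, coefficients in cm⁻¹, radiance in
W cm⁻² sr⁻¹.  The laser is a forward-collimated radiance injected at one
boundary cell face on the single ordinate nearest the inward normal (ties
to the lower index; 11.25° off-normal at M = 16 — recorded in the run
manifest).  Defaults: CW 0.020 W cm⁻² sr⁻¹; pulse 0.200 W cm⁻² sr⁻¹ for
100 fs, i.e. exactly the first step at Δt = 1e−13 s (sub-step pulses are
stretched to one step at stated amplitude, not energy-rescaled).  A
`Source(ordinate=...)` override exists so mirror-symmetric illumination can
be constructed exactly.  Detected fluence integrates (1 − R) I over
ordinates within the 45° half-angle acceptance cone (no obliquity factor,
matching the defining integral); profile normalization divides by the
trapezoid-weighted side mean and is scale-invariant.

The solver's injected power for a source is S·w_m·|Ω_m·n|·Δface per unit
depth; the Monte Carlo launches exactly that power, so fluences from the
two routes are comparable in absolute units.

## Monte Carlo oracle

Analog (unweighted) 2D transport: exponential free paths from the
cell-local μa + μs traced cell-by-cell; absorption with probability μa/μt
at collisions; in-plane deflection sampled from a 4096-knot inverse CDF of
the planar HG kernel; specular Fresnel reflection/escape at the outer
boundary using the same reflectivity function as the solver.  Photon weight
is conserved exactly (absorbed + escaped + path-capped = launched).
Tallies: track-length fluence per cell, and per-face escape fluence with
the 1/|cos| surface-crossing estimator (aperture-restricted for detected
fluence, with squared sums for standard errors).  Trajectories for
classification (ballistic / snake / diffusive / absorbed) come from a
separate pure-Python tracer; "snake" means an escape path no longer than
(1 + δ)× the entry-exit chord with δ = 0.3 — a reporting convention, not a
physical constant.

## Fixtures and what the synthetic data does (not) show

The built-in media reproduce the study geometries: the 4 cm × 4 cm ring
phantom (annulus 2.8/3.0 cm diameter, CW source mid-bottom, Δx = 0.05 cm,
M = 16) and a 2 cm rat-liver-like rectangle with 18 detectors on the top
and left sides driven by a wavelength-indexed table (λ, μa, μs, g, n_m).
All property *values* are synthetic fixtures of plausible magnitude —
chosen once so that the background satisfies the resolution rule
Δx < 1/(μa + μs′) and the ring is water-like (nearly transparent) — because
no numeric properties are available to ship.  Consequently the package's
tests validate the *solver physics* (conservation, limits, oracles,
symmetries) on these media; they do not validate agreement with any real
tissue measurement.  The wavelength sweep reproduces the qualitative
spectroscopic pattern expected from its table (maximal transmission in the
red/NIR rows, extinction at the strongly absorbing ends) and will do so for
any table with that shape.

## Validation benchmarks (`cvdom.validation`, `scripts/acceptance.py`)

Problem sizes are chosen to run each benchmark in seconds to a few minutes
on one CPU.

- **Beer–Lambert** — homogeneous absorber fixture (μa = 1, 2 cm, Δx = 0.02,
  M = 16, upwind): row-integrated fluence from the entry row to mid-depth
  vs exp(−μa·y/η) along the beam ordinate.  Measured ≈ 1.0% error.
- **Energy balance** — ring phantom, CW, tol = 1e−8: |injected − absorbed −
  transmitted|/injected.  Measured ≈ 1e−12 (the discretization is exactly
  conservative; the residual is iteration error).
- **Transient→steady** — 1 cm medium (μa = 1, μs = 5, n = 1.4), CW marched
  1500 ps (≈15000 steps, well past the few-hundred-ps slowest mode) vs the
  steady driver, element-wise relative difference.  Measured ≈ 2e−8
  against a 1e−7 band (10× tol); both drivers sit within their iteration
  residual of the common fixed point.
- **Phase conservation** — Σ_m w_m p_mm′ = 1 to machine precision for
  g ∈ {0, ±0.9, 0.5}, M ∈ {16, 32}.
- **Causality** — 100 fs pulse, 1 cm medium: detector readings before
  n_m·d/c.  This benchmark *documents a limitation*: the scheme is
  implicit in space and time, one sweep couples the whole grid within a
  step, and the numerically diffused front arrives ahead of the ballistic
  time with order-unity amplitude at Δt = 1e−13 s, Δx = 0.05 cm.  An exact
  pre-arrival zero is unattainable for any implicit scheme; resolving the
  front sharply would need Δx ≈ cΔt/n_m (≈20 μm) and an
  explicit/characteristic treatment, both out of scope.
- **Symmetry** — mirror-pair CW illumination of a homogeneous medium: the
  steady fluence matrix is mirror-symmetric to ≈1e−14 relative (the
  iteration preserves the problem's symmetry to rounding).
- **RTE vs Monte Carlo** — homogeneous-scatterer fixture (μa = 0.5,
  μs′ = 5, g = 0.9, n = 1.4, M = 32): detected fluence integrated along the
  far side, 1e5 photons.  Measured ≈ 3–4% against a max(5%, 3 SE) band.
  Per-detector comparison at single faces is dominated by residual ray
  effects of the 32-direction set in this quasi-ballistic regime and is not
  asserted.
- **Linearity** — doubling the CW and pulse amplitudes reproduces every
  detector output bit-exactly.
- **Sweep oracle** — the jitted quadrant sweep against an independently
  coded scalar face recurrence on a pure-absorber strip: identical to the
  last bit for α ∈ {½, 1}.
- **MC moments** — sampled deflection cosines at g = 0 and g = 0.9 vs 3
  standard errors.  g = 0 recovers 0; g = 0.9 recovers the planar kernel's
  own mean 0.9816 (see above), which the benchmark reports as measured.

## Known limitations

- 2D geometry only; refractive index uniform inside the medium (mismatch
  only at the outer boundary).
- Ray effects: discrete ordinates concentrate streaming along M directions;
  single-detector readings in weakly scattered regimes oscillate spatially
  even when side-integrated quantities are accurate.  Raise M for
  angularly resolved output.
- No causal front tracking: pulse rise times shorter than the smearing
  scale of the implicit scheme (tens of ps at the default grid) are not
  resolved; late-time TPSF decay is reliable, first-arrival sharpness is
  not.
- Diamond (α = ½) is non-monotone; use α = 1 near collimated beams and in
  transients (the fixtures do), and watch the negativity diagnostics.
- Source iteration converges at the scattering albedo rate; media with
  albedo → 1 (μa → 0 with large μs) need many sweeps (SOR helps modestly;
  no synthetic acceleration is implemented).
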