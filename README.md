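# cvdom — 2D radiative transfer in tissue-like media

`cvdom` is a forward model of visible and near-infrared light transport in
biological tissue: a control-volume discrete-ordinates (CVDOM) solver for the
two-dimensional time-dependent radiative transfer equation (RTE), with
Henyey–Greenstein scattering, Fresnel index-mismatch boundaries, collimated
continuous-wave (CW) and femtosecond-pulse sources, boundary detector
readout, and an independent analog Monte Carlo photon walk for
cross-validation.  It is aimed at diffuse optical spectroscopy and
tomography work where the diffusion approximation fails — thin samples,
low-scattering "void-like" regions, strongly absorbing wavelengths, and
early-time pulse propagation.

## Model

The monochromatic radiance I(**r**, **Ω**, t) (W cm⁻² sr⁻¹) obeys

    (n/c) ∂I/∂t + Ω·∇I + (μa + μs) I = μs ∫ p(Ω·Ω′) I(Ω′) dΩ′ + S,

with absorption and scattering coefficients μa, μs (cm⁻¹), refractive index
n, and the Henyey–Greenstein phase function

    p(cos θ) = (1 − g²) / (4π (1 + g² − 2g cos θ)^{3/2}).

Directions live on the unit circle: M constant-weight ordinates
Ω_m = (ξ_m, η_m) at angles (m + ½)·2π/M with Σ w_m = 2π.  Space is a uniform
rectangular grid of Δx·Δy cells; the transport operator is integrated over
each cell and closed with the interpolation I_P = α I_E + (1−α) I_W
(α = ½ diamond, α = 1 upwind).  Time uses an implicit three-level
second-order stencil, (3I^{n+1} − 4I^n + I^{n−1})/2Δt.  Each step is solved
by source iteration with SOR over-relaxation (ρ = 1.1), sweeping the four
direction quadrants in upwind order; the steady state is the same fixed
point with the time terms dropped.  At the outer boundary,

    I(r_b, Ω, t) = S(r_b, Ω, t) + R(Ω) · I(r_b, Ω_ref, t),   n·Ω < 0,

with Fresnel reflectivity R (R = 1 beyond the critical angle
arcsin(n₀/n_m)).  Detectors report the detected fluence rate
Φ_d = Σ w_m (1 − R_m) I_m over ordinates within a 45° acceptance cone of
the outward normal.

The Monte Carlo oracle propagates analog photons with cell-local
exponential free paths, absorption probability μa/μt per collision,
in-plane HG deflections sampled by inverse CDF from the *same* kernel the
solver discretizes, and the same Fresnel boundary — so the two methods can
be compared in absolute units.

## Worked example

A 1 cm × 1 cm homogeneous medium (μa = 0.5 cm⁻¹, μs = 50 cm⁻¹, g = 0.9,
n = 1.4), a 20 mW cm⁻² sr⁻¹ CW beam at the middle of the bottom side,
five detectors across the top:

```python
import numpy as np
from cvdom import *

grid = build_grid(1.0, 1.0, 0.05, 0.05)
medium = MediumMap.homogeneous(grid, OpticalProperties(mu_a=0.5, mu_s=50.0, g=0.9),
                               n_m=1.4)
problem = TransportProblem(medium, ordinates=32,
                           sources=[make_cw_source("bottom", offset_cm=0.5)],
                           detectors=uniform_detectors("top", grid, 5),
                           config=SolverConfig(alpha=1.0))
result = run_steady(problem)
balance = result.energy_balance()
print(f"converged in {result.iterations} sweeps")
print(f"injected {balance.injected*1e6:.3f} uW, absorbed {balance.absorbed*1e6:.3f} uW, "
      f"transmitted {balance.transmitted*1e6:.3f} uW "
      f"(residual {balance.residual_fraction:.1e})")
profile = result.detector_profile("top")
print("top-side detected fluence (W cm^-2):", np.array2string(profile, precision=3))
print("normalized:", np.array2string(normalize_profile(profile), precision=3))
mc = simulate_photons(medium, problem.sources[0], n_photons=100_000, seed=1,
                      ordinates=problem.ordinates)
print(f"MC check: {mc.absorbed_fraction:.3f} absorbed, {mc.escaped_fraction:.3f} escaped")
```

prints

```
converged in 396 sweeps
injected 195.404 uW, absorbed 81.744 uW, transmitted 113.660 uW (residual 2.6e-08)
top-side detected fluence (W cm^-2): [3.016e-05 4.032e-05 7.062e-05 6.139e-05 4.437e-05]
normalized: [0.72  0.962 1.685 1.464 1.059]
MC check: 0.421 absorbed, 0.579 escaped
```

The energy budget closes to 3 parts in 10⁸; the detected profile peaks near
the source axis (the collimated beam maps to the discrete ordinate 11.25°
off-normal, hence the slight rightward skew); and the deterministic absorbed
fraction (81.744/195.404 = 0.418) matches the Monte Carlo estimate (0.421).

## Command line

```bash
cvdom fixtures --out configs/          # write the built-in study media
cvdom solve --config configs/ring_phantom.yaml --mode steady --out run/
cvdom solve --config configs/rat_liver_like.yaml --mode transient \
      --t-max-ps 100 --snapshots-ps 10,50 --out run_t/
cvdom mc --config configs/homogeneous_scatterer.yaml --photons 100000 \
      --seed 1 --trajectories 50 --out mc/
cvdom sweep --out sweep/               # steady runs across a wavelength table
```

Every run writes a JSON manifest with all resolved settings, detector CSVs,
and fluence matrices as HDF5.  Built-in media include a 4 cm × 4 cm phantom
with a water-filled void-like ring (inner/outer diameter 2.8/3.0 cm) and a
rat-liver-like rectangle driven by a wavelength-indexed property table; the
shipped property values are synthetic fixtures of plausible magnitude, meant
to be replaced with literature values via the config.

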