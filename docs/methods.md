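# Methods

## The physical problem

Organ-on-a-chip (OOC) devices culture cells on a porous membrane inside a
perfused microchannel, and the wall shear stress at that membrane is a key
physiological control variable. Culture media based on DMEM supplemented with
fetal bovine serum (FBS) are shear thinning at the shear rates such devices
operate at (roughly 0.01–1 s⁻¹): their apparent viscosity at low shear rate
is one to two orders of magnitude above the constant value (≈9.3×10⁻⁴ Pa·s)
conventionally assumed in the literature. Treating the medium as Newtonian
therefore underestimates the membrane shear stress by roughly an order of
magnitude at typical perfusion rates. This package implements the full
modelling chain needed to quantify the effect: rheology fitting, a nonlinear
channel-flow solver, closed-form design formulas, and the measurement-side
pipeline that converts layered velocimetry into membrane shear stress.

## Viscosity model

The medium is modelled as a generalized Newtonian (Ostwald–de Waele
power-law) fluid,

```
mu(gamma_dot) = K * gamma_dot**(n - 1),        tau = K * gamma_dot**n
```

with flow consistency `K` [Pa·sⁿ] and flow index `n` (dimensionless; `n = 1`
Newtonian, `n < 1` shear thinning). Two parameters are deliberate: richer
models (Carreau etc.) fix the zero-shear divergence but add parameters that
over-fit noisy rheometer sweeps. The model is trusted over the measured
window 0.01–100 s⁻¹; evaluation below the window is allowed but warned
about.

**Regularisation.** The power law diverges as `gamma_dot -> 0`, which occurs
by symmetry at the channel centreline. Evaluation clamps the shear rate at
`gamma_eps = 1e-6 s⁻¹` (configurable), four decades below the trusted
window. At operating drives the clamp touches only a thin centreline sliver
and has no measurable effect on the flow or the wall stress. One subtlety is
worth recording: the clamp breaks the exact homogeneity of the pure power
law at *vanishingly small* drives (when the entire field sits below
`gamma_eps`, the solve degenerates to a Newtonian one). The flow-rate driven
solver therefore always runs its reference solve at the thin-channel
pressure-gradient estimate for the *requested* flow rate, so the reference
field lives in the power-law regime, and scaling-law checks use drives well
above the clamp.

**Fitting.** `fit_power_law` is ordinary least squares on
`ln mu = ln K + (n-1) ln gamma_dot`. Log–log fitting weights each measured
decade evenly (the data span four decades and look linear on log–log axes)
and is exact on noiseless power-law data; a nonlinear least-squares option
(`method="nls"`) is provided for users who prefer linear-scale weighting.
Standard errors of `ln K` and `n` and the log-space R² come from the
regression.

Fitted parameters used throughout (medium, K [Pa·sⁿ], n): DMEM+10% FBS
(0.028, 0.31), DMEM+5% FBS (0.037, 0.33), DMEM+1% FBS (0.016, 0.51),
DMEM+10% FBS at 37 °C (0.005, 0.54); Newtonian references: water
(1.0×10⁻³ Pa·s, a 20 °C handbook value, configurable) and the "literature"
constant 9.3×10⁻⁴ Pa·s.

## Channel-flow solver

For steady unidirectional flow in a rectangular duct (width `w` along y,
height `h` along z, membrane at `z = h`) the momentum balance reduces to a
nonlinear Poisson problem on the cross-section:

```
d/dy(mu du/dy) + d/dz(mu du/dz) = -|dp|/L,
gamma_dot = sqrt((du/dy)^2 + (du/dz)^2),   u = 0 on the walls.
```

Inertia is negligible: Re ≲ Q/(νℓ) ≈ 0.17 at 10 µL/min in a 1 mm channel,
so the creeping-flow (Stokes) form is used and `reynolds_number` provides
the guard.

Discretisation is a conservative 5-point finite-difference stencil on a
regular node grid (default spacing 0.02 mm, at least 40 cells across each
dimension); face viscosities use the power law at the mean of the adjacent
nodal shear rates. The nonlinearity is resolved by Picard iteration with
under-relaxation 0.7 (a robust choice for p-Laplacian-type problems with
`p = n + 1` down to `n ≈ 0.3`), relative-update tolerance 10⁻⁸, at most 500
iterations, and each linear pass solved by a sparse direct factorisation. A
Newtonian fluid is detected and solved in a single pass. The velocity field
is initialised with the polynomial bubble
`4 u_scale y z (w-y)(h-z) / (w² h²)` scaled to the thin-channel peak
velocity estimate. Typical run: 40–70 iterations for `n = 0.31` on a 61×64
grid, well under a second per iteration.

**Verification.** Three independent oracles:

* Newtonian limit: the classical Fourier-series duct solution (implemented
  with the parallel-plate part summed exactly so truncation decays
  exponentially; cross-checked against the textbook square-duct conductance
  constant 0.035144). Solver agreement: velocity, flow rate and wall stress
  within 0.1–0.5% on the default grid.
* Thin-channel limit (w/h = 20): mid-width profiles match the closed-form
  parallel-plate power-law solution to <1% for `n = 0.54`.
* Homogeneity: pure power-law solutions at different flow rates collapse
  exactly (velocities ∝ Q, pressure gradient and stresses ∝ Qⁿ); rescaled
  and freshly solved fields agree to <10⁻⁶.

Wall shear stress is `K * gamma_w**n` with the wall shear rate from the
second-order one-sided normal derivative (the tangential derivative vanishes
by no-slip); corner values are exactly zero. Grid halving changes the
membrane `tau_max` by <2%.

**High-shear wall fraction.** The span of the contiguous region around the
wall-stress maximum with `tau >= 0.9 tau_max`, normalised by the wall
length, with linear interpolation at the threshold crossings. On a square
cross-section this fraction grows from 39.3% (Newtonian; exact series value)
through ≈45% (`n = 0.54`) to ≈52% (`n = 0.31`) — shear thinning flattens the
core velocity profile into a plug and widens the uniformly-stressed region
cells actually experience.

## Closed forms and the design formula

The thin-channel (parallel-plate) solutions for velocity, flow rate and wall
stress are implemented as stated closed forms; the two wall-stress forms
(pressure-driven `tau = G h/2`, flow-driven `tau = K (2Q(2+1/n)/(h²w))ⁿ`)
are exact transforms of each other through the flow-rate relation.

The design formula answers the practitioner's question — what flow rate
imposes a target stress `tau` at the base of a channel with `h < w`:

```
Q = h² w * n/(2(1+2n)) * (tau/K)^(1/n) * F(w/h) / S(w/h)
F = 1 - (192/pi^5) (h/w) tanh(pi w / 2h)      (flow-rate side-wall correction)
S = 1 - (8/pi^2) / cosh(pi w / 2h)            (mid-wall stress correction)
```

`F` and `S` are the leading terms of the Newtonian rectangular-duct series;
their ratio is the geometric correction (0 < F/S ≤ 1, increasing to 1 as the
channel widens). The grouping was validated empirically against the full
nonlinear solver: over the four fitted media and aspect ratios 1.5–20 the
realised stress is within 1.7% of target (slightly above it in most cases).
The physically "exact" alternative — applying the stress correction inside
the 1/n power, `F · S^(-1/n)` — is far *worse* (12% at aspect 1.5 for
`n = 0.31`): the Newtonian corrections misestimate the power-law `F` and `S`
individually but their errors cancel in the printed first-power ratio.

**Scaling laws** (verified to solver precision over 10× sweeps):
`tau = C_s h |dp|/L`; `u = (Q/A) f_s(y, z)`; `tau = K C_tau (Q/R³)ⁿ` across
geometrically similar channels. The last exponent is `n`, not `1/n`:
scaling the velocity field by `c` scales shear rates by `c` and stresses by
`cⁿ`, and inverting it gives the `(tau/K)^(1/n)` of the design formula.
Stress is linear in flow rate only for a Newtonian fluid.

## Velocity-stack pipeline

Velocimetry produces one streamwise-velocity field per focal plane; stacking
planes along z gives `u_x(y, z)` at in-plane resolution ≈37 µm and layer
spacing 33 µm (66 µm is commonly used across the channel centre, keeping a
full measurement at 16–25 layers). The pipeline:

1. **Assembly** (`assemble_velocity_stack`): sort layers by z, average 2-D
   (x, y) fields over x (fully developed flow makes x stations replicates),
   validate grids.
2. **Wall location** (`locate_channel_walls`): the wall is where the
   measured velocity drops to zero — linear zero-crossing extrapolation of
   the outermost flowing layers' peak speeds, clipped at one layer spacing
   beyond the last flowing layer. The alternative (placing the wall exactly
   one spacing out) leaves a wall-position error that is a uniform fraction
   of the spacing, which would prevent the recovered stress from improving
   as the spacing shrinks. Side walls are medians of per-layer floor
   crossings, robust to the layer-to-layer jitter of real (slightly jagged)
   walls.
3. **Membrane stress** (`wall_shear_from_stack`): one-sided finite
   difference across the layers nearest the membrane with `u = 0` imposed at
   the estimated wall, then `tau(y) = K gamma_dot(y)ⁿ` with the measured
   rheology, evaluated at the *local* measured shear rate. A three-point
   second-order option exists for accuracy studies.
4. **Profile comparison** (`compare_profiles`): model interpolated to the
   stack's sample stations at chosen width fractions; max and RMS deviations
   are quoted relative to the model's peak velocity and flagged against a
   10% band.

Noise-free recovery error at 33 µm spacing is ≈10% (discretisation of the
near-wall gradient, order δz/h) and falls monotonically to ≈2% at 8 µm.

## Synthetic data generators

No measurement archive exists, so generators emulate the acquisitions'
statistical structure; all are deterministic under one global seed with
per-component substreams.

**Rheometry.** Multiplicative lognormal point noise, default CV 0.10 (a
±20% ≈ 2σ repeatability band around the fit line). Replicate ensembles also
draw per-sample true parameters `K_i = K exp(N(0, 0.07))`,
`n_i = n exp(N(0, 0.02))`: per-point noise alone fixes the ratio of fitted-K
to fitted-n spread through the design matrix and cannot reproduce the
observed sample-to-sample spreads (~20% on K, ~9% on n) jointly; the two
CVs were calibrated once by Monte-Carlo against those figures.

**Velocity stacks.** The solved field sampled on the velocimetry lattice
(guard layers outside the channel; optional two-zone spacing), with three
noise terms matching the identified error sources: (i) per-layer
multiplicative drift, uniform ±7% of the layer (flow fluctuations between
sequentially acquired layers — the "jagged contour" effect); (ii) additive
Gaussian noise with the 4×10⁻⁵ m/s single-frame standard deviation divided
by √(100 frame pairs × 40 streamwise stations averaged into a layer
profile); (iii) rigid per-layer jitter of the side-wall position, uniform
±5% of the width. What the generator does *not* emulate: channel
cross-section non-rectangularity, membrane leakage/permeability, tracer
sedimentation, thixotropic start-up transients, and spatially correlated
velocimetry noise. Passing recovery tests therefore demonstrate the
pipeline's consistency and noise robustness, not immunity to those
systematic effects.

With the full noise model, the recovered membrane `tau_max` stays within the
25% measurement-error envelope in ≥90% of seeds (median error ≈6% for the
body-temperature medium).

## Numerical and design choices, in brief

* SI units internally; helpers convert µL/min and dyne/cm² (1 Pa =
  10 dyne/cm²).
* `solve_for_flow_rate` = one reference solve + exact homogeneity rescale;
  the returned flow rate matches the request to <10⁻⁹ relative.
* Flat stress plateaus: the high-shear fraction walks outward from the
  argmax, so ties inside the plateau are included; linear interpolation
  handles the crossings.
* Degenerate inputs raise typed errors (`InvalidModelError`,
  `InsufficientDataError`, `ConvergenceError` with residual history).
* The membrane is the top wall (`z = h`) by convention; acquisitions with
  inverted orientation pass `membrane="bottom"`.

## Known limitations

* The published simulation table for this device was driven by
  experimentally measured flow rates and per-sample rheology that are not
  archived; at nominal conditions (tabulated ensemble K, n; 4 µL/min) this
  package reproduces the strongly shear-thinning rows within 10% but sits
  ~17% below the moderately thinning rows and ~40% below the Newtonian
  reference row — the latter is fixed by an exact series solution, so the
  gap is in the published inputs, not the solver. The published 25%
  sensitivity of simulated stress to rheology repeatability covers the
  power-law gaps.
* The mid-channel shear rate in a 1 mm square channel at 4 µL/min slightly
  exceeds 1 s⁻¹ for the strongest shear thinner (n = 0.31: ≈1.1 s⁻¹,
  confirmed independently by inverting the design formula), so the often
  quoted "≤1 s⁻¹" operating bound is approximate for that medium.
* Cross-sections are ideal rectangles; no entrance/outlet effects, no
  fluid–structure interaction with the membrane, no time dependence, no
  thixotropy.
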