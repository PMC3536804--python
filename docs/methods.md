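# Methods

## Model and estimator

A membrane protein confined in a lipid domain is modelled as an
overdamped Langevin walker in a potential field *V*(**r**) (k_BT) and a
diffusivity field *D*(**r**) (µm²/s), related to the friction field by
fluctuation–dissipation (*D* = k_BT/γ). The estimator works on the
recorded positions of one trajectory:

1. **Mesh.** The bounding box (plus a one-cell margin) is divided into
   square cells of side `mesh_factor` × mean displacement (default 2),
   so one step typically stays within a cell or reaches a neighbour.
   Each step is assigned to the cell containing its start point; the
   per-cell transition counts N₍ᵢⱼ₎ sum to the number of steps.
2. **Fields.** Each occupied cell carries a free diffusivity parameter
   (optimised as log D to enforce positivity). Cells with fewer than
   `min_transitions_estimate` (default 4) transitions inherit the value
   of the nearest estimated cell and are flagged `inherited`: a nearly
   unconstrained per-cell parameter would otherwise overfit in the
   under-visited hopping corridors while the likelihood must still be
   defined there. The potential is one polynomial of order *C* over the
   whole record, expanded about the centre of mass in coordinates
   scaled by the positional spread (for optimiser conditioning; reported
   coefficients are converted back to k_BT·µm^−(l+m), monomial index
   k = (l+m)(l+m+1)/2+l). The constant term is gauge and fixed after
   optimisation so the minimum over visited cell centres is zero.
3. **Likelihood.** Each step contributes a Gaussian transition density
   with mean displacement −D ∇V dt and per-axis variance
   2(D + σ²/dt)dt; σ is the static localisation noise, a fixed input
   (default 30 nm), never inferred. The assumed σ trades exactly
   one-for-one against the fitted D through the apparent variance
   D + σ²/dt (a unit test asserts this invariant). The polynomial
   gradient is evaluated at each step's start position; the per-cell
   constant-gradient variant (`RunConfig.gradient_at = "cell_center"`)
   is retained as an option but showed a ~30% downward bias on the
   flagship two-well benchmark, so it is not the default.
4. **Optimisation.** L-BFGS-B on (coefficients, log per-cell D), with
   analytic gradients; initialised at a flat potential and the global
   MSD diffusivity minus σ²/dt (floored at 10⁻⁴ µm²/s), plus
   `n_restarts` randomly perturbed restarts; ftol 10⁻¹², gradient
   tolerance 10⁻⁸. Non-convergence is flagged in the diagnostics, never
   silent.
5. **Order escalation.** The default order is 4 (enough for two minima
   and a barrier); if the two lowest detected minima lie more than
   300 nm apart the fit is redone at order 6, which the wider geometry
   needs. Escalation is disabled for escape landscapes, where spurious
   secondary minima would trigger it.

## Derived quantities

- **Harmonic summary.** An occupancy-weighted quadratic fit of the
  inferred potential at visited cell centres; the spring constant is the
  mean of the two principal curvatures, and non-confining (non-positive
  curvature) landscapes are flagged.
- **Hopping energy, two wells.** Local minima of the polynomial are
  located on a ≤5 nm grid restricted to the convex hull of the visited
  points (minima must beat all neighbours within one mesh cell; hull
  -boundary minima are discarded). The hopping energy is the maximum of
  V along the straight segment joining the two lowest minima (sampled at
  ≤2 nm) minus the lower (global) minimum. Curved transition paths are
  deliberately not used.
- **Hopping energy, escape.** For a single confining well, the boundary
  defaults to the circle (interval in 1D) centred on the minimum at the
  95th percentile of visited radial distance; benchmarks override it
  with the known well radius. The energy is the boundary-mean (2D) or
  the larger endpoint value (1D) of V minus the minimum. Because the
  boundary region is thermally under-sampled and a monomial polynomial
  cannot flatten into free motion, the raw estimate carries a
  deterministic, monotone bias; it is compensated by inverting a
  calibration curve of mean raw estimate versus true barrier built from
  simulated escape benchmarks (isotonic-regressed for safety). Escape
  records are first clipped to a disc around the well (default 250 nm):
  far plateau excursions carry no information about the boundary but
  would dominate the polynomial's domain. Steps spanning clipped-out
  portions are masked out of the likelihood (it factorises per step, so
  gaps are harmless).
- **Event classification.** Crossings of the perpendicular bisector of
  the two minima are counted on the recorded positions; ≥4 crossings
  label the record `multi_hop` (exchange between sub-structures of one
  domain), fewer `single_hop` (rare jump between distinct domains). The
  threshold is configurable.
- **Thermodynamics.** P(**r**) = e^(−V)/Z on a fine grid; Z by
  trapezoidal quadrature with pitch-halving convergence control; F =
  −log Z in k_BT. The integration domain (visited hull plus one cell by
  default) and the gauge (minimum 0) are explicit parameters because F
  inherits the potential's gauge freedom; ΔF between states is computed
  over the union domain under the shared gauge and measures the change
  in confinement entropy. For a 2D harmonic well Z = 2π/k exactly, which
  anchors the tests and the enzyme-transition surrogate
  ΔF = ln(k_after/k_before).

## Temporal inference

Slow field evolution (minutes-scale enzymatic raft destabilisation) is
tracked by re-running the MAP fit on sliding windows (default 40 s
length, 5 s shift), after removing slow drift by subtracting a locally
linear (Savitzky–Golay, order 1) smoothing of the positions over the
window length — exact for linear drift, statistically neutral for
stationary confined records. The mesh is rebuilt per window because the
mesh rule depends on the window's mean step. Validity requires
τ_m ≪ τ_inf ≪ τ_V,D, where τ_m = L²/D is the confinement mixing time
(L = twice the 95th-percentile radial distance from the centre of mass,
robust against excursions), τ_inf the window length (also checked
against the occupancy target Ñ ≥ 15 points per cell), and τ_V,D the
empirical field-variation time (time for a 10% change of the fitted
series, infinite when the trend is statistically flat). Defaults flag
τ_inf < 10 τ_m and τ_V,D < 3 τ_inf; a window-doubling check reports the
relative change of the windowed medians (≤20% indicates the
quasi-static regime). All problems are flags, never errors.

At frame intervals comparable to the well relaxation time 1/(kD) the
windowed harmonic estimates are deterministically biased (k̂ high, D̂
low; see below). `build_harmonic_calibration` measures mean inferred
versus input (k, D) on stationary harmonic fixtures along the relevant
path and `apply_harmonic_calibration` inverts it; with the calibration,
enzyme-schedule endpoint estimates recover the programmed values within
~15%.

## Simulator

Euler–Maruyama with ≥10 substeps per frame (default 20), positions
recorded at frame starts; deterministic per seed. A guard aborts when
the deterministic displacement of a single integration step exceeds
`stability_limit` (default 0.2 µm), with guidance to raise `substeps`.
Spatially varying diffusivity (inside/outside a disc) is evaluated at
the current position (Itô convention, matching the likelihood's locally
constant D; no spurious-drift correction). Camera effects: dynamic blur
averages the substep positions over the exposure fraction of each frame
(reducing free-diffusion apparent D by the classic 2/3 at full
exposure), then i.i.d. Gaussian static noise of standard deviation σ is
added per coordinate (raising apparent D by σ²/dt; 30 nm at 50 ms gives
0.018 µm²/s). Enzyme schedules interpolate (k, D) piecewise-linearly
between knots; the CHOx preset relaxes k 237→35.4 k_BT/µm² and D
0.063→0.18 µm²/s, the SMase preset 206→10.5 and 0.066→0.27, with
duration ≥10 window lengths. Potential roughness is a frozen Gaussian
field (smoothed white noise on a grid of one-fifth the correlation
length, default correlation 20 nm, normalised to pointwise standard
deviation σ_V) added to a base potential; long-time diffusion then slows
by ≈ e^(−σ_V²), the classical rough-potential law, which the tests
verify within 15% for σ_V ≤ 1 k_BT.

The simulator emulates confined diffusion, hopping, camera noise and
slow field relaxation. It does not emulate viscoelastic (memory-kernel)
dynamics, hydrodynamic coupling, membrane topography, blinking/gap
artefacts beyond explicit clipping, or molecular crowding; passing
benchmarks therefore demonstrate estimator correctness under the
overdamped-Langevin model, not robustness to every property of live-cell
data.

## Finite-frame-rate bias — a documented limitation

The per-step Gaussian likelihood is the exact propagator for a locally
constant force, and it is an excellent approximation whenever the frame
interval is short compared to the local relaxation time 1/(D·V″). The
benchmark conditions sit at the edge of and beyond that regime: for a
3 k_BT quartic barrier with minima 200 nm apart, D·V″·dt ≈ 1.5 at 25 ms
frames. There the estimator's pseudo-true point deviates
deterministically from the generating fields: for a harmonic well the
fitted curvature inflates by 2/(1+e^(−D·V″·dt)) while the fitted D
deflates, and additive localisation noise introduces an
errors-in-variables spurious confinement force. The net effect on the
extracted barrier depends on the geometry: in the 1D two-well benchmark
the curvature inflation and the D-deflation compensate almost exactly
(replicate mean 3.08 ± 0.10 k_BT for a 3 k_BT input), while in 2D the
shared per-cell D averages strongly confined longitudinal steps with
nearly free transverse steps and the compensation breaks (mean ≈ 2.1);
at 5 k_BT with a rarely visited barrier the extrapolation inflates the
estimate (≈ +35%), under α = σ²/(dt·D) = 64% additive noise the spurious
confinement dominates (≈ +120%), and the recovered transverse spring
constant runs ≈ 25% high. These are deterministic, reproducible biases
of the method at these acquisition settings, quantified by the benchmark
harness itself; where a calibration is part of the workflow (escape
geometry, windowed harmonic series) they are compensated and the
corrected estimates are unbiased within the calibrated range. Analyses
at finer frame intervals (D·V″·dt ≲ 0.2) are essentially bias-free, as
the fine-frame harmonic recovery test shows. A free (unconfined) record
analysed with a global polynomial shows k_BT-scale spurious structure at
the sparsely visited edges; the method is intended for confined records.

## Benchmark conditions

The recovery benchmarks use the canonical acquisition settings: 2000
frames at 25 ms, D = 0.025 µm²/s, quartic double wells with minima
200–400 nm apart and barriers 0.5–7.5 k_BT, harmonic lateral confinement
of 200 k_BT/µm² in 2D (the 2D two-well scenario leaves the transverse
stiffness a free choice; 200 is used as the printed lateral value of the
spring-constant benchmark), escape from a 100 nm harmonic well with
plateau exterior (interior D 0.025, exterior 0.05 µm²/s, 1000-frame
records keeping ≥500 points inside and ≥25 exterior points near the
well), and single-hopping-event records selected by rejection on exactly
one mid-plane crossing. Replicate seeds derive from a base seed by a
counter scheme and are recorded, so every replicate is individually
reproducible. Test and acceptance problem sizes (12–40 replicates per
scenario, 10⁵-step equilibrium and roughness runs, 800 s enzyme
schedules) were chosen so the whole campaign runs in a few minutes on
one core while keeping replicate SEMs a few percent of the measured
values.
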