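# Methods

## Scope and model

`hemolat` simulates pulsatile, incompressible blood flow in idealized
voxelized vessel segments with a D3Q19 lattice-Boltzmann (LB) solver and
reproduces the analysis workflow used to validate cerebral-artery
simulations against transcranial Doppler (TCD) velocimetry: a measured
(here: synthetic) 1-D velocity trace drives a parabolic inlet profile,
the flow is propagated through the vessel, velocities are extracted on
measurement planes, and the per-plane peak velocity is compared with the
measured peak through the relative-difference statistic

    d_r = 100 (v_max_sim − v_max_TCD) / v_max_TCD   [%].

Patient imaging and clinical TCD data are not available, so every input
is generated by the package itself: parametric lumens (straight tube,
torus-segment bend with straight extensions, Y-bifurcation) stand in for
the middle cerebral artery (MCA), and a parametric cardiac waveform
stands in for the Doppler export.

## Solver

**Collision.** Single-relaxation-time (BGK) collisions with the standard
second-order D3Q19 equilibrium

    f_i^eq = w_i ρ [1 + c_i·u/c_s² + (c_i·u)²/(2 c_s⁴) − u²/(2 c_s²)],

c_s² = 1/3 in lattice units. Kinematic viscosity and sound speed follow

    ν = (1/3)(τ̂ − 1/2) Δx²/Δt,      c_s = Δx/(√3 Δt),

so a physical viscosity fixes the relaxation parameter
τ̂ = 1/2 + 3 ν Δt/Δx². Linear stability requires τ̂ > 1/2. Combining the
two relations gives τ̂ − 1/2 = √3 (D/Δx)(Ma/Re); the √3 coefficient is
the self-consistent one and is what the code implements and tests.
All field arithmetic is 64-bit; populations are stored sparsely as
(19, n_fluid) arrays with precomputed pull-streaming index tables.

**Shear rate.** The local shear rate is estimated from the second moment
of the non-equilibrium populations,
S_αβ = −3/(2 τ̂ ρ) Σ_i c_iα c_iβ (f_i − f_i^eq), γ̇ = (2 S:S)^½.
This is the conventional LB estimator; it is local (no finite
differences), works identically for both rheologies, and is the basis of
the wall-shear-stress output WSS = η(γ̇)·γ̇ evaluated at wall-adjacent
fluid sites. Against steady Poiseuille flow the estimator is accurate to
~1% in the bulk and degrades to ~4–5% on the outermost wall ring at 24
voxels per diameter.

**Rheology.** Newtonian blood uses η = 0.004 Pa·s. The Carreau–Yasuda
(CY) law

    (η(γ̇) − η_∞)/(η_0 − η_∞) = (1 + (λγ̇)^a)^((n−1)/a)

uses the parameter set standard for cerebral blood flow: η₀ = 0.16 Pa·s,
η∞ = 0.0035 Pa·s, λ = 8.2 s, a = 0.64, n = 0.2128. The CY coupling is
explicit and lagged by one step: τ̂ is recomputed per site from the
previous step's shear rate and clamped to [0.5 + 10⁻⁶, 10] with a logged
warning (the clamp engages routinely at start-up, where the resting
fluid sits on the zero-shear plateau whose viscosity would imply τ̂ ≫ 10
on fine lattices).

**Walls.** Bouzidi linearly-interpolated bounce-back with the exact
sub-voxel link fraction q ∈ (0, 1] obtained by bisection on the lumen's
analytic signed-distance function (geometries are analytic surfaces, not
meshes, precisely so that q is exact and convergence tests are clean).
Both branches (q < ½, q ≥ ½) are implemented; q = ½ degenerates to
simple bounce-back. Walls are rigid: no moving-wall terms.

**Inlet.** Ladd velocity boundary: bounce-back plus the momentum term
2 w_i ρ₀ (c_i·u)/c_s² on every link crossing the inlet cap, imposing a
time-dependent Dirichlet velocity. The spatial profile is parabolic in
the normalized wall distance d, u(d) = u_c (2d − d²) — the unique
quadratic with u(0) = 0, u(1) = u_c and zero slope at the center — where
u_c is the trace velocity mapped to the profile center (the point
furthest from any wall) and the direction is the inward plane normal.
d is computed from the analytic wall distance normalized by the inlet's
inscribed radius. The discrete alternative (distance to the nearest
non-fluid lattice site of the inlet layer, normalized by its maximum) is
retained as an option; the two coincide as Δx → 0, but at desk
resolutions (12–24 voxels per diameter) the site rule overestimates
near-wall distances by O(Δx), biases the inlet flux by several percent,
and breaks the 2% Poiseuille target, so the analytic rule is the
default. The center site of the discrete rule breaks ties by smallest
lexicographic index.

**Warm-up.** The inlet trace is multiplied by a half-cosine ramp
(1 − cos(πt/T))/2 over the warm-up window — C¹ at both ends — so runs
start from rest without shock waves. Peak-velocity statistics exclude
the warm-up window.

**Outlet.** Open mixed Dirichlet–Neumann condition: in-plane velocity
zero, zero normal gradient of the normal velocity (first-order, one
lattice site along the inward normal), density prescribed at ρ₀ = 1
(the pressure gauge is arbitrary; a single reference density serves all
outlets). Unknown incoming populations are reconstructed as the
equilibrium at (ρ₀, u_n n̂) — u_n extrapolated from the interior stencil
neighbor — **plus the interior neighbor's non-equilibrium part**, and
the site's population vector is then rescaled so its density is exactly
ρ₀. The non-equilibrium term makes the reconstruction second-order and
suppresses the spurious in-plane flow of a pure-equilibrium outlet
(measured: from ~6% of the axial speed down to < 0.1% in the plane
core at 24 voxels per diameter); the exact density pinning anchors the
static pressure and damps an acoustic feedback mode between the two
open ends that otherwise grows in oscillatory (Womersley-type) runs.
The dynamic pressure on the outlet plane is *not* constrained and
varies over the cardiac cycle; the `differential_pressure` extractor
reports it as c_s²(ρ − ρ̄) relative to the instantaneous domain-average
density ρ̄.

**Compressibility guard.** Runs whose peak inlet velocity implies a
lattice Mach number above 0.1 are refused unless explicitly overridden,
since compressibility errors grow as Ma².

## Synthetic data

**Geometries** are voxelized by center sampling (a voxel is fluid iff
its center is inside the analytic surface and strictly inside every
open-end cap; physical position of voxel (i,j,k) is
origin + (index + ½)Δx). Open ends are capped by the inlet/outlet
planes themselves. Default study-scale settings: lumen diameter 2.4 mm
(the MCA scale consistent with Re ≈ 966 at 1.61 m/s and ν = 4×10⁻⁶
m²/s) at Δx = 0.1 mm — 24 voxels per diameter — with Δt chosen to keep
the peak lattice velocity at or below Ma = 0.1.

**Waveforms** emulate a TCD envelope: per cycle, a Gaussian systolic
upstroke to the peak followed by exponential decay to a diastolic
plateau (35% of peak by default). The systolic peak is snapped onto the
sample grid so the trace maximum equals the requested peak exactly when
noise is off. Cycle lengths are the requested mean plus truncated-normal
jitter (±3 sd), emulating the observed per-cycle variability; defaults
follow the measured inflow regime (peak 1.50 m/s, mean cycle 0.894 s,
six cycles). Optional quantization noise, uniform on ±0.0064 m/s,
models the error of velocities transcribed from screen images; it is
off by default. Sampling rate defaults to 100 Hz (instrument rate not
specified by the source measurements; configurable). Any periodic
template satisfying the peak/cycle contracts could be substituted.

What the generator does **not** model: beam spectral broadening,
depth-dependent occlusion and noise, phase misalignment between
sequentially measured depths, or physiologic beat-to-beat waveform
shape variation. Passing tests therefore demonstrate solver and
pipeline correctness under controlled conditions, not robustness to
clinical measurement artifacts.

**Beam registration.** Depth-tagged calibration points are fitted by a
total-least-squares line (SVD principal axis, oriented along increasing
depth); depths map to origin + depth·direction. The RMS perpendicular
residual is always reported so implausible calibration data surfaces in
the fit quality rather than failing silently. Doppler angle correction
divides the measured velocity by |cos θ| (the instrument reports the
projection onto the beam) and refuses |cos θ| ≤ 0.1; the flow-direction
indication (toward/away from the probe) fixes the sign. Note the cosine
model gives a 1.5% underprediction at 10° beam error (1 − cos 10°).

## Velocity scaling

Reduced-velocity runs multiply the inlet trace by s ∈ (0, 1] and the
extracted velocities by 1/s. With geometry, cardiac frequency and fluid
fixed, the Womersley number α = (ωD²/ν)^½ is preserved but Re drops to
s·Re — both cannot be held simultaneously, so the reduced run sits in a
different flow regime. The package quantifies the consequence: in the
Stokes regime (Re ≪ 1) rescaling is exact (measured pointwise
discrepancy < 0.1% between a U and a rescaled U/2 run), while in a
curved tube at Re = 300 vs 150 the rescaled fields disagree by well
over 5% of the plane maximum (measured ≈ 19%), mirroring the loss of
accuracy of reduced-velocity hemodynamic simulations.

## Benchmarks and problem sizes

All solver validation runs are desk-scale, chosen to finish in minutes
on one core while keeping each check in its asymptotic regime:

* Poiseuille: 24 voxels/diameter, Re = 24, tube length 2D, steady state
  detected by velocity-field drift < 10⁻⁶ between 200-step checkpoints.
  Centerline error ≈ 0.6%.
* Grid convergence: Re = 5, tube length 4D, 12 vs 24 voxels/diameter
  under diffusive scaling (u_lat halved with Δx); L2 error against the
  imposed-parabola solution drops at order ≈ 2.
* Womersley: α = 3, 24 voxels/diameter, period 4800 steps, tube length
  1D, analytic Bessel profile imposed at the inlet (ramped over one
  period), mid-tube profiles over the final period compared in relative
  L2 (≈ 2%). The short tube keeps the acoustic transit lag ≪ the period.
* Shear-wave decay: periodic 32-voxel box, amplitude decay rate vs
  ν_eff k² with ν_eff = η(γ̇_RMS)/ρ. For the CY model the unit system is
  chosen so the wave's shear rates sit deep on the zero-shear plateau
  (λγ̇ ~ 10⁻⁵): only where the viscosity the flow actually experiences
  is uniform does the single-exponential closed form apply. Both
  rheologies agree within 0.3%.
* Rescaling: curved tube (bend radius 2.5D, 90°), Re = 0.2 (Stokes,
  12 voxels/diameter) and Re = 300 (16 voxels/diameter).
* Rheology sensitivity: gently curved tube at MCA scale — D = 2.4 mm at
  24 voxels/diameter, bend radius 3D over 60° (MCA-M1-like curvature),
  steady 1.5 m/s inflow, Re = 900 — for Newtonian and CY rheology. The
  developed flow retains a weak Dean-type unsteadiness (a few tenths of
  a percent), so v_max is the maximum over the downstream plane and a
  post-development window (steps 7500–9500), the same plane-and-time
  maximum used for cardiac-cycle comparisons. At these shear rates
  (λγ̇ ~ 10⁴) the CY viscosity sits near its infinite-shear plateau, so
  the plane peak velocity is nearly rheology-independent (measured
  ≈ 0.4%) while low-speed regions differ an order of magnitude more.
  A sharper bend (radius 2D, 90°) at this Re sits at the BGK stability
  edge at desk resolution, which motivated the geometry choice.

## Numerical choices and degenerate inputs

* Plane extraction: trilinear interpolation onto a plane grid of pitch
  Δx; stencil corners in solid voxels get zero weight and the remaining
  weights are renormalized; positions with no fluid support are NaN
  (distinct from zero velocity). The reported quantity is the velocity
  component along the plane normal, in m/s.
* v_max is the maximum over plane positions *and* time after warm-up
  exclusion.
* d_r is rounded half-away-from-zero to one decimal, the convention
  under which every tabulated reference value follows exactly from its
  velocity pair.
* Relaxation parameters outside [0.5 + 10⁻⁶, 10] are clamped (CY) or
  refused (Newtonian, τ̂ ≤ 0.5); a Mach-guard violation at inlet
  registration raises before any stepping.
* Geometry guards: diameters under 8 voxels are refused; bend radius
  must exceed the diameter; zero-diameter or overlapping bifurcation
  daughters are refused. Wall-link search failure (no intersection on a
  cut link) raises an internal consistency error rather than guessing.
* Determinism: the waveform generator is seeded; the solver itself is
  deterministic, and repeated pipeline runs produce identical reports
  (config hash and seed are recorded in the provenance block).

## Known limitations

* BGK stability bounds the desk-scale Reynolds range: at 24
  voxels/diameter the MCA-scale Re ≈ 900 runs sit at τ̂ ≈ 0.5046 and are
  near the stability edge (16 voxels/diameter is unstable at this Re).
  Multiple-relaxation-time or regularized collisions would relax this
  but are out of scope.
* The outlet is a simple open boundary; no peripheral-resistance
  (Windkessel) coupling, so downstream impedance effects on the
  pressure waveform are not modeled.
* Rigid walls; no elastic deformation.
* The outermost wall ring carries O(Δx) artifacts in the shear-rate
  estimator and in-plane outlet velocities; quantities reported at
  planes are dominated by the core flow and are insensitive to this.
* Voxel-center sampling gives O(Δx) lumen-volume error (~2–5% at 24
  voxels/diameter), which converges away under refinement but matters
  for absolute flux comparisons at coarse resolution.
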