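# Methods

## Scope and model

`hemowall` implements the post-imaging stages of a wall-shear hemodynamic
profiling pipeline for large arteries.  Blood is treated as an
incompressible generalized-Newtonian fluid with Carreau viscosity

    mu(gdot) = mu_inf + (mu_zero - mu_inf) * [1 + (lambda*gdot)^2]^((n-1)/2)

with defaults mu_zero = 0.056 Pa s, mu_inf = 0.0035 Pa s, lambda = 3.313 s,
n = 0.568 and density rho = 1060 kg/m^3 — the constants commonly used for
human blood in aortic CFD.  The square is applied to the dimensionless
group (lambda*gdot); n <= 1 (shear-thinning) is enforced unless an explicit
override is set, and the viscosity is provably confined to
[mu_inf, mu_zero].  Note the approach to the infinite-shear plateau is the
power law (lambda*gdot)^(n-1): at gdot = 1e6 1/s the residual gap is still
8.0e-5 Pa s (0.15% of the plateau separation), a property of the model, not
of the implementation.

The flow physics is realized in the one geometry where the governing
equations admit analytic verification: fully developed axisymmetric flow in
a rigid straight tube with no slip,

    rho du/dt = -dp/dx + (1/r) d/dr ( r * mu(|du/dr|) * du/dr ).

This is deliberately a desk-scale stand-in for a 3D patient-specific
finite-volume solve: it shares the governing momentum balance, rheology,
boundary conditions and time-marching protocol, but not secondary flows,
curvature or branching.  The body force is zero.

## Solver numerics

* **Space.** Conservative finite volumes on a radially stretched grid.
  Faces sit midway between nodes; the cell "volume" is the exact annular
  measure (r_{i+1/2}^2 - r_{i-1/2}^2)/2, so the steady Newtonian discrete
  solution is the exact Poiseuille parabola and the discrete wall shear
  G*R/2 is exact to rounding.  The near-wall grid honors the inflation
  prescription (first gap 0.1 mm, 5 layers, growth 1.2 by default); the
  interior continues the geometric progression so spacing is smooth.
* **Time.** Implicit backward Euler at dt = 0.001 s with Picard lagging of
  the viscosity: each step re-evaluates mu(|du/dr|) at the current iterate
  and re-solves the tridiagonal system until the relative velocity update
  falls below 1e-5, capped at 30 iterations per step (non-convergence sets
  a flag and logs; NaN is a hard error).  Three cardiac cycles are marched
  and the last returned, with the max-norm difference between the final two
  cycles reported as `periodicity_error`.
* **Initial state.** By default the march starts from the steady profile at
  the initial pressure gradient rather than from rest.  In pure
  axisymmetric diffusion the start-up transient decays like
  exp(-(mu/rho)*j01^2*t/R^2) — about 7% per cycle at aortic radius — so a
  rest start cannot be periodic after three cycles at alpha ~ 23; a steady
  start removes most of the transient, and the three-cycle protocol is
  quantitatively periodic (<= 1e-3 of peak) for Womersley numbers up to
  about 3.  Validation cases are therefore run at alpha ~ 2-3
  (small-vessel radius, 1 Hz); at aortic alpha = 23 the analytic Womersley
  oracle itself is cross-checked against an independent arbitrary-precision
  Bessel evaluation instead of the marching solver.
* **Flow-driven solves.** When the flow rate is imposed, the pressure
  gradient at each step is obtained by affine superposition: for a frozen
  (Picard-lagged) viscosity the map dpdx -> Q of the implicit step is
  affine, so two linear solves give the exactly matching gradient — the
  converged limit of a secant iteration.  The match is verified per step
  against a 1e-6 relative tolerance.
* **Wall shear.** A three-point one-sided difference on the stretched grid
  (exact for quadratic profiles); reported as a magnitude with a signed
  variant retaining the direction of du/dr.
* **Flow rate.** The exact integral 2*pi*int(r*u)dr of the piecewise-linear
  velocity profile, used both for reporting and for the flow-matching loop.

Measured verification (also enforced by the test suite): steady Poiseuille
wall shear to ~1e-13 relative; Womersley velocity profiles at alpha = 2 to
0.2% L2 at dt = 0.001 s; Carreau steady profile against a stress-inversion
oracle to 5e-5 relative; tau_wall waveforms at dt = 0.005/0.001/0.0005 s
pairwise within 0.8% L2.

## Wall indices

TAWSS is the time average of the WSS magnitude; OSI is
(1 - |int WSS dt| / int |WSS| dt)/2, clipped to [0, 0.5] against round-off;
RRT = 1/((1-2 OSI) TAWSS) and ECAP = OSI/TAWSS.  All integrals use the
trapezoidal rule with periodic closure (a final segment from the last
sample back to the t = 0 value).  Indices are cell-based — areas come from
the triangle cross product, so area weighting is natural; units are SI with
Pa for stress throughout.  Genuine singularities (OSI = 0.5 for RRT,
TAWSS = 0 for ECAP) yield +inf sentinels and are counted in reports, never
NaN; VTK output encodes them as 1e30 with a companion finite-mask array
because VTK-XML readers disagree on IEEE infinities.  An optional
tangential projection strips exporter noise along the cell normal.

## Waveform morphology

The feature extractor takes the systolic peak as the global maximum, the
diastolic minimum as the global minimum, the end-diastolic pressure as the
cycle-end sample, and the dicrotic notch as the most prominent local
minimum within a post-peak window (default 0.4 T, prominence threshold
configurable) — robust on two-hump central waveforms without derivative
heuristics.  Comparisons (mean/max absolute difference, mean absolute
percent error, delta-P) are evaluated after linear resampling onto a common
uniform 1000-point grid; periods must agree to 0.1%.  Pressure I/O is mmHg
with the conversion fixed at 133.322 Pa/mmHg.  The "average error" and
"average pressure difference" of mesh-comparison studies are taken as mean
absolute percent error and mean absolute difference respectively, since no
formula is standard.

## Mesh-independence procedure

Each mesh is compared with its next-coarser neighbor:
100*|v_fine - v_coarse| / max(v_fine, v_coarse), rounded half away from
zero to an integer percent.  Scanning from coarse to fine, the first mesh
within the threshold (3% by default) is selected — the least expensive
acceptable mesh; a joint selection over several parameters takes the finest
of the per-parameter choices.  The normalization by the larger value and
the rounding rule are the unique convention that reproduces all 16 printed
percentage cells of the bundled ten-mesh healthy-aorta reference study, and
that regression is locked in the tests along with the four published
selections (0.4 mm tetra/V_max, 0.6 mm tetra/WSS_max, 0.6 mm poly/V_max,
0.2 mm poly/WSS_max).  Runtime minutes are pass-through metadata, never
computed or asserted.  The bundled table carries the published values
verbatim, including the repeated V_max at 0.2 mm and 1 mm in the polyhedral
family (presumably a typo in the source, preserved as printed).

## Synthetic data: what it emulates and what it does not

The generators are pure functions of `SynthConfig` (seed included) and emit
machine-readable ground truth next to every artifact.

* **Pressure waveform**: a main systolic Gaussian, a broader reflected hump,
  a narrow negative Gaussian (incisura) and the implied diastolic runoff,
  affinely rescaled so max = SBP and min = DBP exactly (defaults 120/80
  mmHg, T = 1 s).  All seven clinical landmarks are present and their
  sample-resolution locations returned.  Seed-jitter moves centers/widths
  a few percent; the dip is deep enough (15% of pulse pressure nominal)
  that it always forms a strict local minimum.
* **Inlet flow**: a sin^2 systolic hump over [0, 2*t_peak] (peak exactly at
  t_peak = 0.15 s) with a small early-diastolic backflow bump, shifted so
  the discrete cycle mean is exactly 0.14 m/s — at diameter 35.88 mm and
  mu = 0.004 Pa s this is Re ~ 1331, laminar.
* **Surfaces**: structured triangulated cylinders (or torus segments) with
  mean edge length within ~10% of the requested 0.2-1.0 mm element size and
  outward normals.  They emulate resolution families only: no arch, no
  branch ostia, and no tetra-vs-polyhedral distinction (that requires a
  volumetric mesher), so the mesh-family label is free text.
* **WSS fields** (analytic mode): per axial band, a unit square wave of
  duty cycle f scaled by a per-band magnitude in 0.5-20 Pa; planted
  OSI = (1-|2f-1|)/2 and TAWSS = magnitude are closed-form.  Sign
  transitions are placed halfway between samples so trapezoidal quadrature
  recovers the planted values exactly — recovery failures therefore
  indicate real pipeline defects, not quadrature noise.  Solver mode maps a
  non-reversing pulse solution along the tube (planted OSI = 0).
* **Mesh studies**: value(h) = v* + C*h^p with counts ~ h^-3 and optional
  seeded noise.

Passing on these inputs demonstrates correctness of the index algebra,
quadrature, selection logic and I/O — not fidelity to secondary-flow
features of real aortas (curvature-driven OSI patterns, branch-flow
splitting), which no axisymmetric or square-wave surrogate exhibits.

## Degenerate inputs and tie-breaks

Cells with identically zero WSS get OSI = 0 and are counted; constant
pressure waveforms yield zero pulse pressure, an absent notch and a
warning; a sign-ambiguous peak delta-P (symmetric oscillation) reports the
signed value of the largest-magnitude sample.  Thresholding uses strict
inequalities; +inf thresholds are legal and give empty "above" masks.
Waveform CSV parsing rejects non-monotone times, NaNs and comma-decimal
locales with the offending line number.

## Problem sizes

Default study conditions: 1 s cycle at dt = 1 ms (1000 steps/cycle, 3
cycles), radial grids of ~50 nodes, surface meshes of ~5k-26k cells at
1.0-0.2 mm, 200 WSS samples per cycle, 1000-sample waveforms.  The full
pipeline completes in well under a minute on one CPU; validation solves in
the test suite use the same protocol at small-vessel radii.

## Known limitations

No turbulence, curvature, branching, fluid-structure interaction or
body-force effects; Casson and temperature-dependent rheologies are out of
scope.  The solver is 1D-radial: it cannot reproduce spatial WSS
heterogeneity, which is why surface index computation is decoupled and fed
by the generators or by external VTK/HDF5 exports.  RRT/ECAP are reported
with sentinels rather than regularized near their singular sets.
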