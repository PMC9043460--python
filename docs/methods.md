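# Methods

## Model overview

The package simulates an ORA-style air-puff measurement as three chained
models — axisymmetric solid mechanics, geometric optics, signal feature
extraction — and inverts the map from biomechanical parameters to device
features with a response-surface regression.

### Solid mechanics

The cornea is an axisymmetric solid bounded by an anterior ellipse with
apical radius *R* and shape factor *p* and a posterior ellipse constructed
so the central thickness is CCT and the limbal thickness CCT + 100 µm.
Defaults that the problem statement leaves open: *p* = 1 (spherical cap;
the apical curvature equals *R* for any *p*, and the parametric ranges do
not vary *p*) and a limbus at x = 5.5 mm (11 mm corneal diameter).  Both
are configurable.  The limbus is fully fixed; the sclera is not modelled.

The material is linear elastic (ν = 0.49, nearly incompressible) with a
third-order Prony shear relaxation; the bulk response is elastic.  This is
the deviatoric/volumetric split customary for time-domain viscoelasticity
in explicit finite-element practice.  Each Prony branch is integrated with
the exponential recurrence that is exact for piecewise-linear strain, so
the branch update is unconditionally stable at any time step.  Density
defaults to 1062 kg/m³ (corneal tissue).

Elements are 4-node axisymmetric quadrilaterals with one-point (reduced)
integration and Flanagan–Belytschko stiffness hourglass control
(coefficient 0.05 of the shear modulus).  Geometry is updated every step
and stored tensors co-rotate with the element spin (Jaumann increment), so
moderate rotations during deep indentation are handled while strains stay
small.  The explicit central-difference step is
`dt = 0.8 · min(area / longest diagonal) / c_d` with `c_d` the dilatational
wave speed — about 0.6 µs for the default 40×4 mesh, i.e. ≈ 42 000 steps
per 25 ms transient.

Loads: the IOP acts on the posterior face as a constant follower pressure
(no fluid–structure interaction); the air puff acts on the anterior face as
a fixed-axis (puff-axis) traction with the Gaussian temporal and spatial
shapes given in the README, evaluated at the current radial position of
each surface point.  The puff amplitude P_max is not published for the
device.  It was calibrated once and frozen at 160 mmHg: the value makes
every cornea in the calibrated parameter box applanate twice within the
25 ms window *and* pass through a concave phase deep enough that the
optical signal drops well below half its peak between the two applanations
(at lower amplitudes the two 50 %-width windows of stiff, high-IOP corneas
merge into one envelope and the widths become meaningless).

### Static solves and the stress-free state

Quasi-static inflation uses dynamic relaxation: damped explicit stepping
(kinetic damping — velocities are zeroed at every kinetic-energy peak) with
the pressure ramped over the first 2000 steps, run until the free-node
residual falls below 10⁻⁶ of the load norm, with early termination when no
sustained progress is made.

Because topography is imaged at the in-vivo IOP, the unloaded geometry is
recovered by a fixed-point pull-back: inflate the current candidate,
subtract the mismatch to the imaged target, repeat.  The correction is
under-relaxed adaptively (Aitken's Δ² rule, factor clipped to [0.05, 1])
and backtracks if a candidate mesh folds; convergence is declared when the
re-inflated apex lands within 10⁻³ mm of the target.

One deliberate modelling choice: the pre-inflation and pull-back use the
**instantaneous** elastic modulus, not the relaxed one.  For strongly
viscoelastic parameter sets the relaxed modulus drops to as little as
0.1 E; at IOP up to 30 mmHg a linear-elastic shell of that stiffness
balloons by several millimetres, which is outside the small-strain regime
the material model assumes (real corneas strain-stiffen long before that)
and drives the inverse pull-back into a snap-through limit point.  The
transient is nevertheless started *fully relaxed*: the stored deviatoric
strain is rescaled by 1/G∞ with all branch variables zero, which reproduces
the converged static stress field exactly, so frame 0 is in equilibrium,
creep-free, and consistent with a cornea that has borne its IOP for a long
time.  (The public `static_inflate` keeps the long-time modulus as its
default; the pipeline passes the instantaneous option explicitly.)

### Optics

Each anterior profile is mirrored about the axis, fitted with a cubic
smoothing spline (zero penalty by default — the FE profiles are noise-free
— with the penalty exposed for rough inputs), and revolved into a surface
of revolution; the oblique beam breaks the optical axisymmetry, so tracing
is fully 3-D.  The transmitter and receiver are 3 mm discs on the plane
11 cm above the undeformed apex, i.e. at a slant distance 11·√2 cm along
the 45° beam, each oriented normal to its chief ray; a flat mirror at the
apex plane maps the beam exactly onto the receiver (intensity 1), which
fixes the geometry unambiguously.  The 3000 rays are laid out on a
deterministic sunflower (Vogel-spiral) disc pattern, so intensities carry
no Monte-Carlo noise and converge to ~10⁻³ by 3000 rays.  Ray–surface
intersections are bracketed on a dense tabulated height profile and
bisected; normals come from the exact spline derivative, reflection is
specular (residual ~10⁻¹⁵ rad), and a single bounce is traced.  Diffuse
reflection, tear-film effects, refraction and multiple bounces are
ignored.  Rays missing the surface or the receiver are counted, never
raised.  The device frame is anchored at the *initial* apex and does not
track the deforming cornea.

### Features

The applanation curve is partitioned at the mechanics-side instant of
maximum apex indentation (robust against micro-peaks in the concave
phase); each side's maximum is refined with a 3-point parabola and its
50 %-height crossings located by linear interpolation.  Applanation
pressures are the temporal puff shape evaluated at the peak times, scaled
by P_max.  Widths are reported in ms and, via a configurable scale (one
unit per 25/400 ms sample by default, i.e. ×16), on the device's unitless
scale.

### Inversion

The sweep samples the six inputs uniformly and independently (matrix
n × 6, seeded); a₂ = a₃ = 0.1 and τ₂ = τ₃ = 10⁻⁴ s are fixed.  The
regression response variables are E/(2.5 E₀), a₁, and lg(τ₁/τ₁₀); the
default basis is the intercept, the seven normalized linear terms and
their squares (cross terms and p-value-based backward elimination are
available but off by default, favouring determinism and conditioning at
small sweep sizes).  Fits are plain least squares with a rank check that
names collinear terms.  The published equations are stored as fixed
coefficient sets and never refit.  Their τ₁ equation is evaluated verbatim
even though its intercept (−5.419) is irreconcilable with the τ₁ magnitude
reported for the same cohort (lg(τ₁/τ₁₀) ≈ +0.5); it is therefore not used
as a numerical gate anywhere.  CCT₀ = 550 µm (the sweep midpoint) is used
for the one equation that needs a CCT normalization, and the τ₁ sweep
upper bound is 0.1 s (the value stated with the ranges; a later restatement
says 0.01 s); both are config-exposed.  Out-of-range clinical inputs warn
rather than fail, since healthy cohorts sit near the range edges.

## Problem sizes used by the test battery

Unit and property tests run on closed forms and small meshes.  The
simulation-backed checks use a 40×4 mesh with 251 output frames and 3000
rays for single runs and one-parameter trend scans, and a 50-run sweep on
a 24×3 mesh with 151 frames and 1200 rays for the regression-recovery
check, where the fitted model recovers the held-out elastic modulus with
R² ≈ 0.9.  Mesh-refinement and ray-count convergence tests bound the
discretization sensitivity (< 2 % apex displacement on mesh doubling,
< 0.02 intensity on ray-count doubling).

## What the synthetic conditions do and do not show

The synthetic curves (two Gaussian peaks) validate the feature extraction
against closed forms; they do not emulate detector noise, tear-film
speckle or the device's proprietary filtering.  The simulated applanation
peaks are lower than real ORA peaks because explicit-dynamics surface
ringing (micrometre-amplitude, millimetre-wavelength) scatters rays away
from the receiver's narrow angular acceptance; peak *heights* are
therefore not outputs (as in the reference analysis), while peak times,
widths and pressures are robust to the ringing.  Passing tests show
internal consistency of the model chain and recoverability of parameters
from its own forward map — not clinical accuracy on real eyes, which the
published cohort equations address only at the level of magnitudes.

## Known limitations and disagreements

- Two qualitative trends disagree with the reference simulation study and
  are deliberately left failing in the acceptance test: (1) simulated p₁
  *increases* with IOP here (a tenser cornea flattens later on the rising
  side of the pressure pulse), consistent with clinical applanation
  tonometry but opposite to the reference's reported sign; (2) w₂ grows
  from τ₁ = 1 ms to 10 ms but shrinks again at τ₁ = 100 ms, where the
  material barely relaxes within the 25 ms window and behaves nearly
  elastically (fast, narrow recovery peak), whereas the reference reports
  a monotone increase.  All other tested trends (p₁, p₂ with E; w₁ with
  τ₁; w₂, p₂ with IOP; hysteresis sign and its elastic-limit collapse)
  match.
- The exact regression coefficients of the published equations are not
  reproducible at desk scale; the scaled-down sweep substitutes a
  property-based recovery check.
- No corneal anisotropy, hyperelasticity, scleral compliance, aqueous
  dynamics or 3-D asymmetry; the air-puff amplitude is a single calibrated
  constant, whereas the device adapts its pulse per eye.
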