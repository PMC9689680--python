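# Methods

This note documents the models, the numerical choices, and what the
synthetic-data validation does and does not demonstrate.

## Units and conventions

Everything is in the N–mm–MPa system (1 MPa = 1 N/mm²); strain rates in
1/s; density in g/mm³ (the surimi card stores 0.00097 g/mm³ = 0.97 g/cm³,
a water-like gel density). Image coordinates are pixel-centered with the
origin top-left, x rightward, y downward; displacements u, v follow the
same signs.

## Stress–strain mechanics

Engineering stress uses the single-wall ring section `F/(wH)` with
`w = (OD − ID)/2`; for the reference ring (OD 40, ID 35, H 20 mm) that is
2.5 × 20 mm. Engineering strain is elongation over the initial ring
length `L₀`, which defaults to the **mean circumference**
π(OD + ID)/2 = 117.81 mm — the standard ring length measure — and is
overridable. A pin displacement u stretches both arms of the ring, so
the elongation is 2u.

The Young modulus is the least-squares slope of true stress vs true
strain over the detected linear region: the longest initial window whose
linear fit has R² ≥ 0.995 (≥ 5 points), then trimmed of trailing points
whose residual exceeds 3× the scatter of the window's first half. The
trim exists because the R² criterion alone tolerates a short run of
post-yield points before it degrades; the residual test snaps the window
edge to the kink. Both thresholds are named constants.

Stage segmentation calls the failure point the **edge of the post-peak
cliff**: the last sample within 2% of the peak stress, provided the
stress subsequently drops by ≥ 50%. Using the last near-peak sample
rather than the argmax keeps the detection from drifting early on noisy
records whose stress grows slowly near failure. Records with no
qualifying drop are flagged not-failed; records with no resolvable
elastic stage (the rigid-plastic simulator's output yields immediately)
get an elastic stage of zero length rather than an error.

## Johnson–Cook model

Flow stress `(A + B ε_p^n)(1 + C ln ε̇*)` with ε̇* the plastic strain
rate over the reference rate ε̇₀. The gel's tests run at strain rates of
order 10⁻² s⁻¹ against ε̇₀ = 1 s⁻¹, where a raw logarithm is ≈ −4.7 and
would drive the flow stress (and the fracture strain) negative. The rate
ratio is therefore clamped at 1 from below — the convention explicit
dynamics codes use — and the raw bracket remains available via
`clamp_rate=False`. The thermal-softening bracket of the full model is
implemented (`jc_flow_stress_thermal`) but disabled by default: gel
tests are isothermal at room temperature.

The damage model integrates plastic strain increments against the
fracture strain (rectangle rule, right endpoint, matching the
incremental form of the damage definition); failure at D = 1. The
trailing `(1 + d₅)` bracket is a constant factor — with temperature
dropped from the model, d₅ acts as a fixed multiplier.

### Fitting

* Hardening (A, B, n): trust-region nonlinear least squares with a fixed
  multi-start over n ∈ {0.2, 0.5, 0.8}; best residual wins. A fitted B
  that is numerically zero flags n as unidentifiable and reports A as
  the mean stress.
* Rate constant C: with (A, B, n) fixed, the bracket is linear in
  ln ε̇*, so C is the through-origin regression slope of
  `σ/(A + B ε_p^n) − 1` on ln ε̇*. All rates at the reference rate make
  the design singular (the clamp pins the bracket at 1) and raise an
  `UnidentifiableError`.
* Damage constants d₁–d₅: nonlinear least squares with d₂, d₃, d₅
  bounded to [0, 0.1] (weakly identified) and d₁, d₄ free. Because d₃
  is small, the data only constrain the product `(d₁ + d₂)(1 + d₅)` — a
  flat ridge along which an unregularized optimizer drifts, attributing
  part of d₁'s magnitude to the nuisance constants. A light ridge
  penalty (weight 0.1) on d₂, d₃, d₅ resolves the ambiguity toward the
  dominant constant d₁, which is the reporting convention for this
  model. The penalty weight only needs to exceed the noise floor of the
  flat direction; it does not bias the identifiable parameters (d₄ is
  untouched, and d₁'s residual bias from absorbing the true near-zero
  d₂, d₅ is ≈ 0.4%).

The damage-recovery design uses fracture strains on a grid of four
triaxialities {0, 1/3, 2/3, 1} × three rates {1, e, e²}·ε̇₀ with 10
replicate observations per cell (120 total) at 2% relative noise.
Replication at this level is what a curve-fitting campaign on replicate
specimens would produce, and is needed for a usable precision on d₄,
whose rate effect (2.1% per e-fold) is comparable to the noise.

## Ring tensile simulation

A zero-dimensional quasi-static closure, not a finite-element model. The
taut-ring kinematics convert pin displacement to membrane strain
(ε_eng = 2u/L₀); the Johnson–Cook law gives the stress; damage
accumulates to failure with the triaxiality fixed at the uniaxial value
1/3 (with d₂ = d₃ = 0.001 this choice moves ε_f by < 0.1%, but it is
explicit).

**Rigid-plastic strain accounting.** The gel's modulus is so low
(E = 0.01719 MPa against A = 0.00833 MPa) that a textbook elastic–plastic
split would put an elastic strain of ≈ 0.48 at the yield stress — nearly
half the kinematic strain at failure — and push the predicted failure
displacement far past the measured band. The simulator instead treats
the specimen as rigid-plastic: all kinematic strain past the yield point
counts as plastic for damage accumulation, and elastic stretch is
neglected in the kinematics. The damage-driving measure is the
**engineering** strain of the taut ring (the natural measure of that
closure; the logarithmic measure is available via
`strain_measure="true"`). Under these choices failure lands at
ε_f·L₀/2 = 20.70 mm (41.4 s at 0.5 mm/s), inside the experimental band
21.5 ± 1.5 mm. Slack take-up at the pins is modeled as zero: strain
accrues from u = 0.

Default time step dt = 0.05 s (0.025 mm of pin travel): halving it moves
the failure displacement by < 0.5%, and a step producing more than 0.01
plastic strain is rejected with an instruction to reduce dt. Because the
strain rate sits below ε̇₀, the clamped rate bracket makes the predicted
failure displacement independent of pin speed.

## Penetration model

`contact_area` implements the standard wetted surfaces: cylinder
(flat tip + engaged wall), sphere (spherical cap, then full ball plus an
R-radius shaft), cone (lateral slant area, then full cone plus base-radius
shaft); the "cone angle" of a conical probe is read as the full apex
angle. Normalized force F/A uses the total wetted area.

`simulate_penetration` is a transparent engineering closure:

    F(z) = σ_flow(z/h_gel, ε̇) · [A_normal(z) + k_shear · A_lateral(z)]

with A_normal the depth-projected tip area and A_lateral the remaining
(inclined/side) wetted area. Two per-shape coefficient sets close the
model: the shear weight k_shear (cone 1.8 > sphere 1.3 > cylinder 1.0 —
inclined surfaces generate more shear per unit area) and a tip
strain-concentration factor (cone 0.70, sphere 0.35, cylinder 0.35) that
scales how fast tip strain approaches the fracture strain. The sharp
cone therefore trips the damage criterion mid-stroke and its force falls
to a 20% residual (the post-breakpoint plateau of a puncture record),
which makes its normalized force collapse with depth, while the blunt
probes survive the 20 mm stroke and their F/A tracks the rising flow
stress. The coefficients were calibrated once to the qualitative
contrasts a gel puncture test shows — peak-force ordering cone > sphere >
cylinder, a conical/cylindrical peak ratio of ≈ 2–4, and the opposite
F/A depth trends — and are exposed in the setup. The model makes no
claim to reproduce finite-element stress magnitudes or contour fields.

## Digital image correlation

Subset matching maximizes the ZNCC — invariant to gain and offset of the
deformed frame — over a ± search-radius window; candidates whose subset
leaves the image are excluded, and grid points with no candidates or no
texture (zero intensity variance) are masked invalid rather than raising.
Exact score ties break deterministically: smallest displacement
magnitude, then row-major order. The optimized matcher (vectorized
sliding windows) is tested for exact agreement with an exhaustive
brute-force ZNCC search wherever the peak margin exceeds float noise.

Subpixel refinement fits a full quadratic to the 3×3 ZNCC neighborhood
of the peak and solves for its stationary point (clamped to ±1 px,
skipped when the Hessian is not negative-definite). A numerically
perfect peak (ZNCC = 1) is returned as-is: refinement could only perturb
an already exact answer, which keeps integer rigid shifts exact.

Strains come from least-squares plane fits of u and v over a
strain-window neighborhood of grid nodes (valid points only, ≥ 3 and
full-rank required), differentiated into the Green–Lagrange tensor —
appropriate for strains approaching 0.5 — with the small-strain tensor
available for comparison. Defaults: subset 21 px, grid spacing 5 px,
search radius 15 px, strain window 5×5 nodes, minimum correlation 0.5.

Sequences are tracked against frame 0 (the reference), with each frame's
search seeded at the previous frame's solution so cumulative motion can
exceed the per-frame search radius.

Measured accuracy on synthetic imagery: integer shifts exact; a 5%
uniform stretch recovered at ≈ 0.08 px RMS (interior, matchable grid
points); plane-fit strain of an exact affine field reproduces the
closed-form tensor to machine precision, and the image-pipeline mean
strain of the 5% stretch is within 2×10⁻³ of the closed form. Grid
points near the image boundary whose true match leaves the frame are
excluded from these accuracy statements — their matches are clamped and
their strain is unreliable, as in any DIC system.

## Synthetic data

Generators are pure functions of (parameters, seed) and embed their
generating truth in metadata. Noise is multiplicative on stress/force
(load-cell error scales with signal; lognormal on force records so they
stay positive) and additive on images (sensor noise does not).

Speckle images are Gaussian blobs (ink dots, dark on a light background)
at uniform random centers with additive Gaussian noise, clipped to the
bit depth; the default density (0.02 blobs/px², σ ∈ [1.5, 3] px) gives
every 21×21 subset texture. At high densities the dark blobs saturate
to black and create flat regions — the small oracle-test images use a
lower density for that reason.

Warped sequences resample the reference bilinearly under analytic warps
(translation, isotropic stretch about the center, and a "ring stretch":
an x-stretch whose amplitude is a Gaussian bump in y centered at 75% of
the image height, emulating the strain concentration near the lower pin
contact of a stretched gel ring). The analytic displacement field is
exact, so accuracy budgets honestly include the bilinear interpolation
error. The ring-stretch schedule's final amplitude solves
s + s²/2 = target Green–Lagrange strain (s = √2 − 1 for a 0.5 target).

## What the synthetic validation does not show

The generators emulate curve shapes, noise structure and speckle
kinematics — not real gel heterogeneity, probe–gel friction, camera
perspective (a tilted camera is not modeled or corrected), lens
distortion, out-of-plane motion, or the spatial stress fields around
pins and probes that only a finite-element model resolves. Passing
tests demonstrate that the estimators and the matcher recover known
ground truth under realistic noise, not that a specific laboratory gel
obeys the Johnson–Cook law.

## Problem sizes

The test and validation runs use desk-scale sizes chosen for tight
feedback loops: 128–160 px images, ≤ 5-frame sequences, 200–900 point
curves, 120-observation damage designs. All sizes are parameters; the
estimators have no intrinsic scale.
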