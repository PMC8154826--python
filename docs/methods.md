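# Methods

## Constitutive models

**Leaflet tissue (intact leaflet, fibrosa, ventricularis).** Fung-type
anisotropic hyperelasticity,

    U = C/2 (e^Q − 1) + K ((J² − 1)/2 − ln J),

with the exponent a quadratic form in the Green–Lagrange strain in the
fiber frame (f circumferential, s radial, n normal). The default form is

    Q = 2 b₁ tr(E) + b₂ E_ff² + b₃ (E_ss² + E_nn² + 2 E_ns²).

The variant with a *linear* fiber term `b₂ E_ff` appears in parts of the
Guccione-derived literature and is kept behind `q_form="as_printed"`; it
makes the energy odd in fiber strain (non-physical in compression), so the
squared form is the default. Both forms are validated against a central
finite-difference gradient of U (≤1e-6 relative, ≥100 random states per
parameter set).

Two structural features of this exponent matter for everything downstream:

* the linear trace term leaves a small reference stress `C·b₁·I`
  (≈2.8e-5 MPa for the intact leaflet) — the reference state is not
  exactly stress-free, and "undeformed" solves relax by ~1e-7 relative;
* there is **no fiber-shear term** (no E_fs, E_fn; the s–n shear carries
  b₃, which is even negative for the fibrosa), so the material has almost
  no shear stiffness of its own. Interior states are stabilised by the
  geometric (stress) stiffness, but free traction-loaded surfaces can
  shear-band; see the cell-stage boundary conditions below.
  `materials.stability_check` scans biaxial strain states for loss of
  tangent positive definiteness.

Parameters (MPa / dimensionless), shipped in
`valvemech/data/material_presets.yaml`:

| preset          | C        | b₁    | b₂    | b₃       | K  |
|-----------------|----------|-------|-------|----------|----|
| intact_leaflet  | 2.82e-3  | 0.01  | 2.84  | 1.97     | 50 |
| fibrosa         | 3.48e-6  | 5.49  | 81.48 | −0.08    | 50 |
| ventricularis   | 5.09e-6  | 4.86  | 5.02  | −1.63e-3 | 50 |

**Spongiosa, VIC, aortic wall.** "Linear, elastic, isotropic" at small
strain, extended to finite strain. Two extensions are implemented:
Saint Venant–Kirchhoff (the simplest objective extension; exposed as
`materials.iso_stress`) and a compressible neo-Hookean law
(`U = μ/2(I₁−3) − μ ln J + λ/2 (ln J)²`). The FE stages use neo-Hookean:
under the diastolic in-plane Green strains (up to ~0.6 radially) SVK loses
its traction-free thickness solution (`λ tr(E)` produces spurious thickness
tension once E_cc+E_rr exceeds ≈0.52 at ν = 0.49) and the layer collapses;
the neo-Hookean response stays well-posed and is small-strain-consistent
with (E_mod, ν). Presets: spongiosa (0.02, 0.49), VIC (9e-4, 0.45), aortic
wall (2.0, 0.3; catalog entry only).

Units are MPa and mm at the organ/tissue scales, MPa and μm at the cell
scale; meshes carry an explicit unit tag and the readers check it.

## FE solver

Quasi-static, total-Lagrangian, 8-node hexahedra, 2×2×2 Gauss quadrature.
The reported quantities are diastolic plateau (equilibrium) states, so an
implicit Newton continuation replaces dynamic time stepping; inertia is
irrelevant at these scales.

* **Quadrature.** Full 2×2×2 integration by default. Selective reduced
  integration of the volumetric part (a classic anti-locking device,
  available as `StaticProblem(..., sri=True)`) proved counterproductive
  here: with deviatoric toe stiffness of order 1e-5 MPa against a bulk
  penalty of 50 MPa, a centre-point-only penalty leaves spurious low-energy
  modes that stall the iteration. Locking under full integration is mild
  for the membrane-like states of interest; the refinement-convergence test
  (central fibrosa stress changing <1 % per subdivision level on a small
  patch) bounds the discretisation error.
* **Newton.** Relative residual tolerance 1e-6 (absolute 1e-10), residual
  backtracking line search, adaptive Levenberg-style damping of the
  direction (near-null shear modes otherwise pollute raw Newton steps),
  step cap at 10 % of the bounding-box diagonal, early stagnation exit,
  and automatic interval halving to depth 8. Damping and line search alter
  only the iteration path; converged states satisfy the undamped residual
  criterion.
* **Follower tractions** track the deformed face area and normal each
  iteration; their exact load stiffness (a non-symmetric rank-2 surface
  term) is assembled into the tangent, which keeps stress-driven solves
  quadratically convergent.
* **Tie constraints** (equal normal displacement over a node set) are
  folded into the reduced unknowns through a sparse selection operator.

## Multiscale couplings

**Organ → tissue (displacements).** The belly patch is cut along parent
element faces (default 5×5×3 = 75 elements); each element is subdivided in
its own parametric space through the trilinear shape functions (default
6×6×2 = 72 children, 75 → 5400 elements; the in-plane/through-thickness
split of the published count 72 is not unique — 6×6×2 matches the ≈0.06 mm
child size and is divisible into the three parent layers). Boundary-node
displacement histories are interpolated with the same shape functions,
which reproduces affine fields exactly. By default only the four lateral
(cut) faces are driven; the physical top/bottom leaflet surfaces stay
traction-free (`boundary="all"` prescribes every boundary node and is used
by the affine-consistency property test).

The tissue stage first brings the stress-free patch to the
start-of-diastole configuration and then tracks the diastolic curve. Two
preload paths are available: `preload="history"` (default) tracks the
organ-scale samples up to the start-of-diastole marker — for the surrogate
this path is isochoric, which keeps the bulk penalty quiescent — while
`preload="linear"` performs the literal N-step linear displacement ramp.
The linear ramp passes through strongly non-isochoric intermediate states
in which the almost-fluid exponential layers make the quasi-static solve
disproportionately expensive; both paths end at the same state.

Layers are labelled from element centroids: fibrosa 41 %, spongiosa 30 %,
ventricularis 29 % of the thickness, fibrosa on the aortic (+z) side;
misaligned subdivision factors raise an error naming compatible choices.
Stresses are reported as volume-weighted Cauchy components over the
fibrosa elements whose in-plane centroid falls in the central third of the
footprint (away from the driven boundary).

**Tissue → cell (stresses).** The cell patch is a structured grid with an
octant-ellipsoid VIC at the symmetry corner, labelled by centroid
membership (staircase boundary, conforming mesh by construction). Default
geometry 100×100×30 μm with VIC axes 10×7.7×7.7 μm at a 1.25 μm grid
(the printed ~5 μm element size cannot resolve 3.85 μm semi-axes on a
staircase grid; the builder requires ≥4 elements across each VIC axis).
FE runs use admissible reduced grids — 19.25²×15.4 μm at 1.925 μm (800
elements) in the tests and demo, 100.1²×30.8 μm at 1.925 μm (~43k
elements) in the `full` profile.

Loading: symmetry planes through the corner, σ_circ(t) and σ_rad(t) from
the tissue stage applied as follower normal tractions on the two opposite
outer faces (thickness face traction-free), phase A ramping to the
start-of-diastole stress. Two robustness devices:

* the loaded faces are kept plane (normal-displacement tie, RVE-style
  loading). Because the Fung exponent has no fiber-shear stiffness, a free
  traction-loaded face develops an unresisted shear band and folds over at
  high stress; the tie suppresses exactly that boundary artifact while the
  resultant equals the same uniform normal traction. The stiffest leaflets
  in the physiological range push the fibrosa to GPa-level stresses (an
  unavoidable consequence of the exponential constants at Green strains of
  0.5–0.6), and converge only with tied faces;
* stress intervals are densified geometrically (strain grows with log σ
  for exponential materials), and each ramp step is seeded with the
  homogeneous material-point solution of the ECM
  (`biaxial.stretches_from_stress`, a damped Newton in stretch space).

The homogeneous round trip (tissue patch of pure fibrosa → stress curves →
all-ECM cell patch) reproduces the tissue stretches within 0.5 %; the cell
response is insensitive (≪1 %) to halving/doubling the VIC modulus, as the
ECM/VIC stiffness discontinuity, not its magnitude, controls the fields.

## Cellular aspect ratio

The deformed VIC half-axes are tracked at the outermost VIC-material node
on each symmetry axis; Normal CAR = circumferential / normal axis, Radial
CAR = circumferential / radial axis (both equal the resting ratio
10/7.7 ≈ 1.3 at the reference state, up to one element of staircase
error). Under any homogeneous deformation the measured CAR equals the
closed-form ratio of stretched reference axes exactly; this is the
property the discretisation is tested against.

## Synthetic organ surrogate: scope

The generator stands in for a subject-specific aortic-root simulation
(image-based anatomy, leaflet contact/coaptation, transvalvular pressure,
wall pre-stress are all out of scope). It emulates exactly what the
downstream stages consume: an affine, isochoric belly-patch displacement
history u(x,t) = (Λ(t) − I)x whose in-plane Green strains follow a
smoothstep rise of the transvalvular load to a configurable peak at peak
diastole (defaults 0.33 circumferential / 0.41 radial, ranges 0.31–0.35
and 0.23–0.59), then a gentle plateau; 30 frames per cycle; a
start-of-diastole marker at the half-rise frame; an optional
through-thickness bending gradient (off by default; J ≡ 1 exactly when
off). Thickness profile: 0.4289 mm at the belly rising to 1.2 mm at the
attachment edge and free margin (quadratic in the normalised distance from
the belly).

Because the surrogate field is affine and noise-free, passing tests show
that the *transfer machinery* is exact and the solvers are consistent —
not that subject-specific strain or stress magnitudes are reproduced.
Fibrosa stress levels are whatever the published constitutive constants
imply at the prescribed strains (tens of MPa at mid-range strains, GPa at
the extreme radial end), and the cell↔organ circumferential relationship
is deterministic rather than scattered; the multi-leaflet demo therefore
asserts the qualitative anisotropic contrast (strong positive radial
regression, narrow circumferential band), not published R² values, which
derive from three private anatomies.

## Problem sizes and profiles

The `reduced` profile (default) runs a 600-element tissue patch (2×2×2
refinement) and an 800-element cell patch; the `demo` profile used by the
nine-leaflet regression keeps the 75-element patch with the same cell
grid; `full` runs the 5400-element tissue patch and the ~43k-element cell
patch. Diastole is tracked at every third frame in the reduced profiles
(marked frames — start of diastole, peak — are always kept).

## Known limitations

* Trilinear hexes with full integration lock mildly as ν → 0.5; the bulk
  penalty K = 50 MPa keeps |J−1| ~ 1e-5 at material points but the layered
  patch tolerances are percent-level, not locking-free.
* The staircase VIC boundary concentrates the interface stress at corners;
  interface peak values are mesh-dependent (the stress-raiser property is
  asserted as an inequality, not a magnitude).
* Stress measure ambiguity: generated/fitted biaxial data are PK2 vs
  stretch; extracted tissue and cell loads are Cauchy. Both measures are
  exposed, since the published magnitudes do not name theirs.
* The cell stage assumes the two in-plane normal stresses suffice (shear
  tractions neglected), which is what makes the three symmetry planes
  usable.
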