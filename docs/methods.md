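# Methods

## The model

The internal urethral sphincter is idealised as a two-dimensional
cross-section under plane stress: a circular lumen of radius `lumen_radius`
surrounded by a ring of dense connective tissue (the transitional
epithelium, thickness `epithelium_thickness`) and a spongy stratum (lamina
propria) out to a mildly oval outer boundary.  The spongy stratum is divided
into four parts: two open V-notches along the lateral axis separate the
upper and lower halves except for a bonded "bound" segment exactly 1 mm long
adjacent to the epithelium on each side, and the left/right parts within
each half are fully bonded.  In the diseased configurations the two lower
parts are fibrotic.  Surgical decompression is modelled as 0–7 circular
holes of radius 0.5 mm on an arc at mid-thickness of the fibrotic stratum,
equally spaced over the fibrotic sector minus a one-hole-diameter margin at
each end; the staggered variant alternates hole centres between two arcs
0.6 mm apart radially.  All interfaces are perfect (shared mesh nodes).

The section is loaded by a uniform intraluminal pressure applied on the
deformed lumen boundary (follower load), default 1960 Pa in 16 equal
increments, or swept over 196–2584 Pa in 196 Pa steps.  The domain is fixed
through two pinned points on the outer boundary at the top and bottom of the
vertical symmetry axis; by default both displacement components are pinned
at both points.  Holes and the outer boundary are traction-free.  Unit
out-of-plane thickness is assumed (the areas and the loss/recovery ratios
are thickness-independent).

## Constitutive model

All tissues are 5-parameter Mooney–Rivlin solids,
`W = C10 (I1b-3) + C01 (I2b-3) + C20 (I1b-3)^2 + C02 (I2b-3)^2 +
C11 (I1b-3)(I2b-3) + (1/d1)(J-1)^2`, with the published constants for dense
connective, spongy and fibrotic tissue (fibrotic = 10× the spongy deviatoric
coefficients; `d1 = 8e-7 1/Pa` for all three, i.e. a volumetric stiffness
`2/d1 = 2.5 MPa` — quasi-incompressible next to the shear moduli of
0.34–10.3 kPa).

The invariants are the *isochoric* ones (`I1b = J^{-2/3} I1`,
`I2b = J^{-4/3} I2`).  This is a deliberate design choice: evaluated on
total invariants the same polynomial carries a spurious isotropic reference
pre-stress `S(I) = (2 C10 + 4 C01) I` (about 0.5 kPa for spongy tissue, 15
kPa for dense connective) and an out-of-equilibrium undeformed state; the
isochoric split is the form the commercial hyperelastic plane elements
implement and gives an exactly stress-free, energy-free reference.  The
total-invariant variant remains available (`isochoric=False`) for
sensitivity studies.

Stress (second Piola–Kirchhoff) and the consistent tangent are derived
symbolically from `W` at import time and compiled to vectorised numpy
kernels, so they are exact derivatives of the implemented energy; the test
suite verifies them against central finite differences to 1e-6 relative.
Plane stress is enforced per quadrature point by a guarded scalar
Newton/bisection iteration on the through-thickness stretch (bracket
`lam3 in (0.05, 20)`; stress tolerance `1e-10 mu0`, falling back to a
1e-13-relative bracket width at large stretches where floating-point noise
in the kernel exceeds the nominal stress tolerance — a loose root here
would contaminate the global residual).  The condensed in-plane tangent
includes the `d lam3/dC` term.

## Meshing

A force-equilibrium (Persson–Strang) generator triangulates the domain on
analytic signed-distance functions, with boundary points seeded on the
exact lumen/hole/outer curves and a deterministic seeded rejection sampling
of the interior — meshing is reproducible bit for bit.  Two-level
refinement: `h_coarse` caps every element edge, `h_fine` caps edges in the
dense-connective band (plus 0.25 mm surroundings) and in a 0.2 mm band
around each hole; the generator re-triangulates with a shrunken size field
if an equilibrium edge overshoots a cap, so the caps are hard.  Elements
are 6-node quadratic triangles by default (3-node linear behind a flag);
midside nodes of boundary edges are snapped back onto the analytic curves.
Distortion is monitored as the displaced maximum corner angle (limit 160°,
strict inequality; inverted elements always count); the remediation policy
is step halving, then mesh regeneration at 0.75× size with a restart of the
load program — a full mid-solve remesh with state transfer is deliberately
not implemented.

## Solver

Total-Lagrangian displacement FEM, 3-point quadrature, sparse direct
factorisation.  The uniform pressure on the closed lumen loop is
conservative — the follower nodal forces are exactly the gradient of
`p * A(u)` under the shared edge quadrature — so equilibria are stationary
points of `Pi(u) = int W dV - p A(u)` and the assembled residual is its
exact gradient.  Each Newton iteration solves with the tangent whose
per-quadrature-point material block is eigenvalue-clamped to be positive
definite (a no-op wherever the response is elliptic), takes the full step
whenever it contracts the residual, and otherwise backtracks preferring
steps that both lower `Pi` (Armijo) and contract the residual; convergence
is declared on the exact residual at `1e-8` of the external load norm.

### Wrinkling and stabilised continuation

A central finding of this implementation: under the published constants the
dense connective tissue loses strong ellipticity (rank-one convexity) at a
principal stretch of about 1.28 on its working stress path, and the spongy
tissue at equibiaxial stretch about 1.17.  For the circular-lumen geometry
this caps the cleanly convergent lumen-area ratio at roughly 1.6 — beyond
it the stiff ring wants to wrinkle at the mesh scale and no discrete
equilibrium is reachable by any line-searched Newton scheme we tried
(including energy minimisation; the landscape becomes rugged and
mesh-dependent).  Load levels beyond the threshold are traversed with
spring-anchored stabilised continuation — artificial springs to the last
converged state, the smallest working spring factor, re-anchored
pseudo-transient steps as the deepest fallback — mirroring the "nonlinear
stabilization" of commercial codes.  At every recorded load level the
solver first attempts to relax back onto the clean equilibrium; when that
is unattainable the stabilised state is recorded **with its stabilisation
force ratio** (spring force / external load) in the convergence log, so a
reader can always tell which numbers carry artificial support and how much.
Recorded ratios at 1960 Pa are typically a few percent up to ~15%.  This
is also why
published absolute areas at high pressure should be read as
solver-regularised quantities rather than exact equilibria — in this
package and, by the same argument, in any solver using these constants at
these stretches.

### Boundary conditions

Default: both displacement components pinned at both outer poles.  Besides
fixing the rigid-body modes this suppresses the rigid vertical drift of the
sane half, which is part of how fibrotic restraint expresses itself in the
opening metrics.  A minimal 3-DOF variant and a symmetry variant (used by
the Lamé verification, where pinning full points would perturb the radial
field) are available through `SolverSettings.bc_mode`.

## Post-processing

The deformed lumen area is the signed shoelace integral over the deformed
intraluminal boundary with curved-edge (quadratic) correction; loss and
recovery are `delta_l = 100 (A_i - A_P0)/A_H0` and
`delta_r = 100 (A_i - A_H0)/A_H0` (the loss is normalised by the fibrotic
baseline, exactly as in the study design).  Principal fields use the Cauchy
stress and, by default, logarithmic (Hencky) strain of the principal
stretches including the out-of-plane one (Green–Lagrange behind a flag);
the per-point "maximum principal" includes the zero out-of-plane stress of
plane stress.  Boundary profiles sample the quadrature point of the owning
element nearest each lumen edge, ordered clockwise by deformed arc length
and split at the sane/fibrotic interface of the undeformed tags.

## Calibration and default parameters

The source geometry is an unpublished histological section, so the default
dimensions are free parameters calibrated once: lumen radius 1.75 mm,
epithelium thickness 0.4 mm, outer radius 4.2 mm with 5% ovality, V-notch
half-angle 0.14 rad, bound length exactly 1 mm.  With these, the sane case
at 1960 Pa opens to about 16.4 mm² — inside ±20% of the published 18.09 mm²
— while staying near the ellipticity cap described above.  An
`outer_center_offset` parameter can additionally thin the wall below the
lumen (the histology shows a markedly non-concentric outline); it is off by
default.

What the calibrated model does *not* reproduce, and why, is documented
honestly: the published loss of the untreated fibrotic case (−44.8%)
requires the sane case to open ≥35% more than the fibrotic one.  Under
these constants that contrast only arises beyond the wrinkling threshold,
where our recorded states are stabilised rather than exact equilibria and
the contrast is much weaker (about −10 to −15% at the default calibration).
The *orderings* — fibrotic < drilled < sane, recovery increasing with hole
count, staggered beating aligned, monotone pressure–area curves with the
drilled case bracketed — are the robust, reproducible content of the
simulation and are what the acceptance checks assert quantitatively.

## Problem sizes and tolerances

Package defaults use `h_coarse = 5e-4 m`, `h_fine = 2.5e-4 m` (roughly
2500–4000 elements) and 16 load increments (finer steps reduce the
per-increment spring bias of the stabilised continuation); the acceptance
script and suite use 7e-4/3.5e-4.  These desk-scale sizes were chosen as
the package's working resolution; the design-basis sizes (2e-4/1e-4) and
the source's own sizes (1e-4/5e-5) are single config switches.  A
mesh-convergence gate (sane-case area, size-halving, low pressure) is part
of `verify --level full`.  Newton tolerance 1e-8 relative to the load norm;
mesh caps are hard; all randomness is a single fixed internal seed in the
mesh generator's rejection sampling, so end-to-end runs are byte-identical.

## Known limitations

- 2D plane stress; no contact (the notch faces and collapsing lumen can
  interpenetrate at extreme loads), no anisotropy, no viscoelasticity, no
  active contraction.
- The published constants are non-elliptic at working stretches (see
  above); absolute areas at 1960 Pa and beyond depend on the stabilisation
  policy and mesh scale.  Principal-field extrema are reported
  qualitatively only.
- The synthetic geometry is a calibrated idealisation of an unpublished
  section; passing tests show internal consistency and the robustness of
  the orderings, not anatomical fidelity.
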