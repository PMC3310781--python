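# Methods

This note records the models, numerical methods, parameter choices and
limitations behind `mnpmap`. SI units throughout; `z` is the axial
(ultrasound beam / force) direction and the last array axis; 2D arrays
are ordered `(y, z)`, 3D arrays `(x, y, z)`.

## Coil magnetostatics

The excitation system is a coaxial, concentric Helmholtz/Maxwell pair of
equal radius `a` centered at the origin. Axial quantities use the
two-loop closed forms: the Helmholtz field is the sum of the single-loop
on-axis fields, the Maxwell gradient their opposed-current derivative. At
the optimal spacings the dimensionless center coefficients are exact:

- Helmholtz, `d = a`: `B_z(0)·a/(μ₀nI) = (4/5)^{3/2} = 0.7155…` (0.716)
- Maxwell, `d = √3a`: `GR_z(0)·a²/(μ₀nI) = (3√3/2)(4/7)^{5/2} = 0.6413…` (0.641)

Off axis, a single loop's field uses the complete-elliptic-integral
closed form (`scipy.special.ellipk/ellipe`); evaluation on the wire
circle raises. The axial gradient off axis — where no tractable closed
derivative exists — is evaluated by central differences of the elliptic
form with step `10⁻⁵·a`; the step is far below the field's variation
scale (`~a`), so the `O(h²)` truncation error is ~10 significant figures
below the value. On-axis cross-checks against the closed forms and a
10⁴-segment Biot–Savart midpoint quadrature hold to better than 10⁻⁶
relative.

**Magnetization model.** Particles carry a specific saturated moment
`M_sat` (default regime threshold 0.4 T, the field at which typical
iron-oxide particles are essentially saturated; `M_sat = 20 A·m²/kg` is
the conservative end of the 20–40 range). Below threshold the moment is
the mass-susceptibility law `χ|B|/μ₀`, clipped at saturation; no
smooth interpolation between regimes is attempted, because every
quantitative use of the model operates at saturation. The force on a
load is `F = (m·∇)B` with `m` pinned along +z by the dominant Helmholtz
field, i.e. `F = m_z ∂B/∂z`.

**Force uniformity over the imaging volume.** The imaging region is the
cube of side `2a/3`. The optimal Maxwell gradient alone droops by 3.1%
at `|z| = a/3` (an even profile — this is the useful uniformity). The
*combined* force field is less benign: the Helmholtz pair's own axial
gradient is odd (`∝ z³` near the center) and, when the Helmholtz current
is 10× the Maxwell current, it dominates near the cube edges, making the
total force profile asymmetric there (frozen regression value: max axial
deviation ≈ 1.6× the center force). The uniformity report is therefore
descriptive — no pass/fail threshold is claimed — and quantitative
force mapping should treat only the central region, or subtract the
known magnetizing-coil gradient.

## Phantoms (the synthetic-data source)

The phantoms emulate the study conditions of breast-tissue-scale
magnetomotive imaging:

- 2D: 10 cm × 10 cm, one circular inclusion (D = 10 mm, centered) or two
  (10 mm + 5 mm, placed symmetrically about the center, 2.5 cm apart —
  the in-plane positions are a free choice recorded in the run config).
  Plane strain, consistent with long cylindrical inclusions.
- 3D: 10 cm × 10 cm × 6 cm with a centered spherical inclusion,
  D ∈ [5, 40] mm.
- Material: E = 10 kPa default (range 5–30 kPa in the stiffness sweeps),
  ν = 0.495, ρ = 1000 kg/m³ (carried but unused in the static solve).
  Background and inclusion share the same stiffness.
- Load: uniform axial body-force density inside the inclusions, zero
  outside, so the inclusions represent regions of uniform particle
  density. Force amplitudes are calibrated to a 0.1% peak axial strain
  (the optimum strain for ultrasound speckle tracking) or to a 10 μm
  peak displacement (the practical measurement floor).

Masks are rasterized by the voxel-center-in-shape rule: deterministic,
convergent (first order in `h`), with total applied force exactly
`density × voxel count × voxel volume`. Default grids: 201×201 in 2D
(h ≈ 0.5 mm) and 51×51×31 in 3D (h ≈ 2 mm) — sizes chosen so a full
experiment suite runs on one desktop core in minutes; the verification
solves below use finer dedicated grids.

Optional Gaussian noise (axial component only, seeded generator) emulates
the finite displacement precision of elastography; it is off by default
since the reference maps are noise-free. What the phantoms deliberately
do not emulate: speckle decorrelation and spatially correlated tracking
errors, viscoelasticity, heterogeneous stiffness, particle-tissue
decoupling, and physiological motion — so passing tests demonstrate the
mathematical consistency of the pipeline, not robustness on in vivo data.

## Forward solver

The static Navier equation is discretized with displacement-based Q1
finite elements (bilinear quads / trilinear hexes), one element per
voxel. Near-incompressibility causes volumetric locking for plain Q1;
the volumetric (`λ`) term is therefore integrated at the element
centroid only (selective reduced integration) while the shear term uses
full 2×2(×2) Gauss quadrature. On uniform box meshes this is
algebraically identical to the mixed Q1/P0 displacement–pressure element
with the pressure condensed out, so both `incompressibility_treatment`
options share one code path. A locking check confirms the ν-dependence:
the center response ratio between ν = 0.495 and ν = 0.45 matches the
analytic ball-solution ratio to 0.3%.

**Boundary conditions.** The reference condition is `bottom_fixed`: the
phantom rests on its bottom (z = 0) face, fully clamped, all other faces
traction-free — the physically natural support against the +z body
force; the choice is recorded in every output's provenance tag.
`all_fixed` clamps every face (sensitivity checks), and `prescribed`
imposes given nodal displacements on all faces (verification, below).

**Linear solves.** 2D systems (~8×10⁴ dof) go to sparse LU; 3D systems
use Jacobi-preconditioned conjugate gradients at relative tolerance
10⁻⁸ (the SRI operator is symmetric positive definite after constraint
elimination). Superposition and force/stiffness scaling hold to solver
tolerance; the 2D peak displacement changes by 1.5% when `h` is halved
from 1 mm to 0.5 mm.

**Verification against the loaded-ball solution.** The Kelvin point
force solution, superposed over a uniformly loaded ball, has a closed
form everywhere via the ball's Newtonian and biharmonic potentials
(`mnpmap.kelvin`, itself validated against direct kernel quadrature).
The solver check loads a D = 10 mm sphere at the center of a 10 cm cube
(61³ voxels) and imposes the analytic infinite-medium field on the box
boundary — the standard way to verify an interior solution against a
free-space benchmark without confounding it with the finite-domain
boundary effect (which is itself ~5–10% at this domain/sphere ratio).
Measured center-displacement error: −1.2%.

## Inverse mapping

Both estimators differentiate the displacement with 3-point central
second differences (mixed terms by nested central first differences).
The one-voxel boundary ring where the stencils do not fit is flagged
invalid and zeroed rather than filled with one-sided differences, which
would amplify noise; all metrics respect the valid mask.

- Axial-only (practical) estimator:
  `F_z = −G(∂²u_z/∂y² + ∂²u_z/∂z²)` — only what a single-plane axial
  acquisition supports. The elevational (x) second derivative is
  omitted; a 2D dataset has no x-term by construction.
- Full estimator: `F_z = −G∇²u_z − G/(1−2ν)·∂_z(∇·u)`, requiring all
  components; `ν = 0.5` is rejected explicitly.

`G` and `ν` are taken as known and uniform — the method presumes prior
knowledge of stiffness (e.g. from elastography); no elasticity
estimation is performed, and no regularized deconvolution beyond direct
differentiation.

**Metrics.** The interior mean of a recovered map uses the inclusion
mask eroded by 2 voxels: the stencil radius (1 voxel) plus the half-voxel
rasterization jitter of the mask boundary contaminate up to 2 voxels, and
the metric is meant to report the recovered plateau, not the boundary
smear (with 1-voxel erosion the smear alone biases the full-map mean by
~+10%; with 2 voxels the bias is ~1%). The halo metric is
`max |F_z|` over a background shell (outside the mask, within 2
equivalent radii of its centroid) divided by the interior mean of
`|F_z|`; a 2-voxel guard band just outside the mask is excluded from the
shell so the metric measures the *physical* halo — which extends over a
fraction of the inclusion radius — rather than the stencil smear that
any estimator produces at the force discontinuity. Both windows imply a
resolution floor: halo/smear separation is meaningful only when the
inclusion diameter spans ≥ 20 voxels, which is why the double-inclusion
studies run at h = 0.25 mm (grid 401) so the 5 mm inclusion is as well
resolved as the 10 mm one at the default grid.

**The amplitude attenuation of the axial-only estimator.** In the
near-incompressible limit the dropped divergence term is not small: the
interior pressure gradient of a uniformly loaded disk (plane strain)
equals exactly half the applied force density (for a ball, one third),
so the axial-only map's interior plateau is `~0.50×` the applied force
at ν = 0.495 (measured 0.503–0.504; frozen as a regression value).
The estimator remains exactly linear in the applied force (R² = 1 to
solver tolerance, relative intercept < 10⁻¹⁰), so relative
quantification — the practical goal — is unaffected; absolute
quantification requires the known geometric factor or the full
inversion. The halo ordering (full < axial-only) holds on every tested
phantom once the resolution floor is respected.

## Experiments and reproducibility

Every experiment writes its fully resolved parameter set (`params.yaml`)
and metrics (`metrics.yaml`); re-running from the serialized parameters
reproduces the metrics bitwise (direct solves) or to solver tolerance
(CG paths). Quantities that exist only as figures in the source
literature (total-force levels, halo magnitudes) are computed once by
this implementation and frozen as regression values, labeled as
implementation-derived. The 3D total-force sweeps run at the reduced
grid (41×41×25 for the stiffness sweep, 31×31×19 for the size-sweep
regression) — at these sizes the full suite stays desk-scale; the exact
sweep grid is part of each frozen value's provenance. The stiffness
sweep confirms `F_total ∝ E` to 10⁻¹³ (operator linearity); the size
sweep gives `F_total(40 mm)/F_total(10 mm) ≈ 3.9`, i.e. total force
grows ~linearly with D (ball solution: `u_peak ∝ fR²/G`,
`F_total ∝ fR³` ⇒ `F_total ∝ R` at fixed peak displacement) — weak
compared with the volume scaling `∝ D³` of a fixed force density.

## Known limitations

- Static, small-strain, linear elasticity only; no dynamics, gravity,
  viscoelasticity or contact.
- The forward/inverse agreement is at the physics level (benchmarks,
  convergence, self-consistency), not a node-for-node match of any
  particular commercial FEM discretization.
- The coil model treats loops as filamentary and ignores inductance,
  resistance, heating and vibration — at the 10⁴-ampere-turn scale these
  are the dominant engineering obstacles in practice.
- The density conversion assumes a perfectly uniform gradient over the
  region of interest and full mechanical coupling between particles and
  tissue.
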