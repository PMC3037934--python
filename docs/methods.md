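# Methods

## Model

`thermograde` treats the spatial distribution of Young's modulus as the
solution of a steady-state heat-conduction problem. Measured moduli at
discrete sites are converted to surrogate "temperatures" through a strictly
increasing linear map, imposed as Dirichlet values at seed nodes, and
propagated through the mesh by solving Laplace's equation with every other
boundary face insulated. The resulting C⁰ nodal temperature field is mapped
back to a nodal modulus field, which then drives a linear isotropic
elasticity solve. No claim is made that diffusion is the physical mechanism
behind stiffness variation in bone; conduction is used purely as a smooth,
boundary-respecting spatial interpolant between known values — heat flows
only through the connected material, so the interpolation follows the
geometry (e.g. around a foramen) instead of cutting across voids, which is
what distinguishes it from generic kernel interpolation in ℝ³.

The surrogate temperature is inert mechanically: the coefficient of thermal
expansion is identically zero throughout, so no thermoelastic strain term
exists anywhere in the package.

### The modulus ↔ temperature map

The default map is proportional through the origin, anchored at
(50 °C, 17.3 GPa): E(T) = (17.3 GPa / 50 °C) · T. Proportionality is the
simplest strictly increasing linear map consistent with a single published
anchor; an affine mode (nonzero intercept) is provided for generality and
must remain increasing and positive over its range of use. Because the map
is monotone, the modulus field inherits the temperature field's bounds: on
meshes where the discrete maximum principle holds, graded moduli stay
within the seeded modulus range.

### Conductivity

With pure Dirichlet seed data and insulated exterior, the steady-state
solution is invariant to uniformly rescaling the conductivity k; the
default is the arbitrary 1.0 W·m⁻¹·K⁻¹, and the invariance is verified
numerically (k = 1 vs k = 250) in the acceptance suite. Per-region
conductivities are accepted (heterogeneous k does change the field) but the
default is uniform.

### Elements and assembly

Only 4-node linear tetrahedra are supported, rejected loudly otherwise.
Shape-function gradients are constant per element, so the conduction
element matrix is k·V·GGᵀ and the elasticity element matrix BᵀC(E, ν)BV.
The stiffness is linear in E and B is constant, so evaluating E at the
element barycenter (the mean of the four nodal values — the default
`centroid` quadrature) integrates a linearly varying modulus *exactly*; the
`four_point` rule (standard degree-2 barycentric points) is provided to
demonstrate that it changes nothing for linear fields. Elasticity uses the
pure displacement formulation with no locking mitigation; ν ≤ 0.36 in the
bundled property table keeps volumetric locking mild, and the
incompressible limit ν ≥ 0.5 is rejected.

### Constraints and solvers

Dirichlet data (seed temperatures, prescribed displacements) are imposed by
row/column elimination with a load-vector correction, never by penalty:
constrained values are exact to machine precision and the reduced system
stays symmetric positive definite. Both physics share one solver policy:
sparse direct factorization up to 200 000 nodes, diagonal-preconditioned
conjugate gradient (relative tolerance 1e-10) above. A connected mesh
component without any seed, or a structural model whose constraints leave
rigid-body modes, raises an explicit error rather than returning garbage.

### Material modes

* **uniform_isotropic** — cortical (17.3 GPa, ν 0.28) / trabecular
  (0.64 GPa, ν 0.28), split by region name (labels matching
  "trabecular"/"trabecular bone", case-insensitive).
* **regional_isotropic** — each tet takes its region's row from a material
  table; the packaged `table1_strait2005.csv` carries the 17 regional
  isotropic records for macaque cranial bone (E from 0.64 to 20.8 GPa).
  Shear modulus is always derived, G = E/(2(1+ν)), never independent.
* **thermally_graded** — the full workflow above. Two genuinely open design
  points are resolved as package defaults, both switchable:
  * *Trabecular regions are not graded by default* (`grade_trabecular=False`):
    they keep the discrete uniform trabecular properties while the graded
    field applies elsewhere. This keeps the sharply softer trabecular
    compartment from being smeared into the cortex by the interpolation and
    makes a constant-seed graded run coincide exactly with the uniform run.
  * *Poisson's ratio is a global constant 0.28 by default* (the
    cortical/neurocranial value), with `nu_policy="regional"` taking each
    region's table value. ν varies far less than E across the table
    (0.21–0.36) and the strain quantities of interest are dominated by E.

## Strain conventions

Strain tensors are stored with tensor shear components (ε_xy = γ_xy/2);
conversions to engineering shear happen only in Voigt assembly and I/O.
Principal strains are sorted descending. **Maximum shear strain is the
engineering value γ_max = ε₁ − ε₃** — twice the tensor maximum shear. This
is the convention under which rosette strain-gauge analyses report "maximum
shear strain", hence the one comparable with the in vivo bone-strain
literature; it is stated here prominently because published comparisons
rarely define it. Probe reports are in microstrain.

Probes are evaluated either in the containing element (constant strain of a
linear tet; error if the point is outside the mesh) or by snapping to the
nearest node and volume-weighting the adjacent element tensors before
eigendecomposition (snap distance logged in the report). Both modes are
provided because published probe values rarely state which was used.

## Point seeds and mesh dependence

The continuum Laplace problem with Dirichlet data at isolated points is
ill-posed in 3-D: the discrete solution near a point seed depends on the
local mesh resolution and does not converge under refinement. The package
therefore makes no convergence claim for point seeds; it offers
`patch_radius` on the seed set, which extends each seed value to every node
within that radius and regularises the constraint, while defaulting to the
single-node behaviour. Fields *between* seeds are well behaved, and all
bound/equivalence properties hold regardless.

## Fixtures and what the tests show

All test geometry is generated programmatically:

* **Structured bars** use the 6-tet Kuhn split of each hex cell (all six
  tets share the cell's main diagonal), chosen over the 5-tet split because
  it conforms face-to-face without parity alternation. With cubic cells the
  tets are nonobtuse, the conduction matrix is an M-matrix, and the discrete
  maximum principle holds exactly — the setting in which the bound checks
  are asserted.
* **The hemispherical shell** (cortical shell over trabecular core, flat
  base) is a synthetic desk-scale stand-in for cranial geometry, built by
  radially mapping a structured half-cube onto the half-ball. The map sends
  ‖·‖∞ level sets to spheres, so with the default radius ratio the
  cortical/trabecular interface is resolved exactly by the grid; the outer
  surface is faceted, so region volumes match the analytic hemisphere
  values only to a few percent at the default refinement.

What these fixtures emulate: multi-region geometry, curved two-material
interfaces, seeds sparse relative to mesh size. What they do not: real
cranial topology (orbits, sinuses, sutures), CT-derived geometry and
element counts (hundreds of thousands of polyhedra), physiological muscle
load distributions, or orthotropy — the scalar temperature field cannot
grade a second-order material tensor, so regionally orthotropic models are
out of scope by construction. Passing tests therefore demonstrate the
correctness of the machinery (assembly, constraints, grading, strain
extraction) and its exact structural properties (linearity, equivalences,
invariances), not the fidelity of any particular anatomical model.

## Problem sizes and numerical choices

The verification suite runs on deliberately small problems chosen to make
the checked properties exact or analytic: bars of 48–768 tets, the shell at
refinement 1 (1 536 tets, 405 nodes). The graded-bar oracle uses 32 axial
elements, where the midpoint-rule modulus sampling puts the FE tip
displacement within 0.004 % of the analytic ln 2 value (the 1 % acceptance
bound is met from 16 elements on). Tie-breaks: nearest-node queries resolve
ties to the lowest node index; negative-volume tets read from files are
repaired by swapping two nodes; duplicate seeds with agreeing values
collapse, with conflicting values rejected. Degenerate inputs (zero-volume
tets, empty meshes, unseeded components, ν ≥ 0.5, non-positive mapped
moduli) raise typed errors naming the offending entity.

## Known limitations

* Isotropic grading only; orthotropic constants and material axes cannot be
  represented by a scalar surrogate field.
* Point-seed solutions are mesh-dependent near the seeds (see above).
* Linear tets are stiff in bending and lock as ν → 0.5; no enhanced-strain
  or mixed formulation is included.
* Loads are nodal forces (or pre-integrated uniform face tractions); no
  body forces or pressure-follower loads.
* Obtuse tets can produce small legitimate maximum-principle violations;
  `check_bounds` reports rather than prevents them.
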