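# Methods

This note documents the models, numerical choices and limitations behind
`cardiomesh`, in the order the pipeline runs.

## Coordinate and image conventions

Label images are axis-aligned integer voxel grids with spacing and origin
in millimetres; voxel *centers* sit at `origin + (index + 0.5) * spacing`.
Oblique NIfTI/NRRD orientations are rejected rather than resampled so the
voxel-to-world map stays exact and containment tests are unambiguous.
Labels are unsigned 16-bit with 0 reserved for background; region names
travel in a JSON sidecar because neither NIfTI nor NRRD standardizes them.

## Synthetic phantom

The phantom emulates a tagged biventricular segmentation at clinical
resolution (~1–1.5 mm isotropic).  The LV is a thick-walled ellipsoidal
shell centred at the origin; the RV is a thinner shell offset laterally
whose overlap with the LV region is relabelled LV, which produces the
crescent-shaped RV and a septal RV endocardium lying on the LV epicardial
ellipsoid.  Both shells are truncated by a flat base plane at constant z
(apex at −z).  Default dimensions approximate an adult heart at end
diastole: LV epicardial semi-axes 30×30×45 mm with a 10 mm wall, RV shell
32×28×40 mm with a 4 mm free wall offset 22 mm towards +x, 75 % of the
long axis retained below the base cut, 1 mm voxels.  The test suite and
pipeline benchmarks use a half-size variant (LV 16×16×24 mm, 5 mm wall) so
meshing- and solver-heavy stages stay fast; geometry-only checks use the
full-size phantom.

Boundary noise emulates staircase/segmentation artifacts: every voxel with
a differently-labelled 6-neighbour is independently relabelled, with
probability p, to a uniformly chosen differing neighbour's label, decided
against the original image (simultaneous update) and driven by one seed.
This produces boundary jitter of about one voxel; it does not emulate
larger-scale segmentation errors (missing structures, topology errors), so
passing tests say nothing about robustness to those.

Every analytic surface has a signed-distance evaluator (closest point on
an axis-aligned ellipsoid via bisection on the Lagrange multiplier,
accurate to ~1e-12), which is what allows the smoothing and rasterization
stages to be scored against ground truth.  Truncated-ellipsoid volumes use
the exact cross-section antiderivative πab(z − z³/3c²) + 2πabc/3.

## Surface extraction

Per tag, the binary indicator on the voxel-center lattice is contoured at
isovalue 0.5.  Instead of the classic cube case table we split each lattice
cell into the six Kuhn tetrahedra and contour per tetrahedron: on binary
data every vertex lands exactly on a lattice-edge midpoint, the
1-inside/3-inside cases are unambiguous, and the single ambiguous case
(2-in/2-out quad) is split along the diagonal through the lexicographically
smallest lattice-edge vertex key.  That rule is invariant under
inside/outside exchange, so two tags abutting across a cell that contains
only those two materials triangulate the interface *identically*, and
"redundant interface removal" becomes exact: coincident faces are found by
hashing vertex triples (vertices deduplicated at 1e-6 mm) and collapsed to
one face carrying the (inner, outer) tag pair.  At three-material cells the
per-tag surfaces are not complementary and their faces are kept separately
with outer label 0; each tag's surface remains closed regardless.

A "blocky" mode emits the raw voxel faces (squares split along the
diagonal through the smallest corner id, again shared between the two
sides).  Its divergence-theorem volume equals the voxel count times the
voxel volume exactly, anchoring the rasterization round-trip tests.
Blocky surfaces of regions that touch themselves diagonally can carry
edges with four incident faces; they are watertight in the parity sense
(every edge bounds an even number of faces), which is the precondition the
rasterizer actually needs, while marching-mode surfaces are strictly
manifold.

Consequence of midpoint vertices: surface area carries a constant
lattice-orientation factor (~1.27 for a sphere) independent of resolution;
enclosed volume is accurate to well under 1 %.  Area comparisons are
therefore made across resolutions of the same method, not against analytic
areas.

## Constrained variational smoothing

Objective: ‖L X‖²_F over vertex positions X, with L the uniform "umbrella"
graph Laplacian (row i: x_i − mean of neighbours; cotangent weights
optional behind the same config).  Constraint: per-vertex axis-aligned box
of half-width 0.5 voxel (per axis for anisotropic voxels) centred at the
initial position; a Euclidean-ball variant exists for sensitivity checks.
The box makes projection exact and trivially cheap, and enforces the
half-voxel guarantee *exactly* — projection is the final step of every
iteration, and the reported maximum displacement is measured on the
returned vertices.

Solvers: monotone accelerated projected gradient (FISTA with adaptive
restart; step from a power-iteration estimate of ‖LᵀL‖; best iterate is
kept, so the reported objective never increases) and ADMM (sparse LU on
2LᵀL + ρI).  The problem separates per coordinate, which is exploited only
in the verification oracle: scipy's dense bounded least squares solves
each axis independently, and both solvers must match it to 1e-6 relative
on toy surfaces.  Convergence criterion: relative objective decrease below
`tolerance` (default 1e-8) between accepted iterates, capped at
`max_iterations` (default 2000; non-convergence returns the best iterate
with a flag rather than failing).

## Rasterization

Each target voxel center is classified against every tag's closed surface
by parity of crossings along a −x ray.  Crossings are accumulated per
(y, z) column; point-in-projected-triangle uses symbolic perturbation of
the sample by (ε, ε²), making the decision the first nonzero of
[edge function, −d_v, d_u] — deterministic and consistent across faces
sharing an edge or vertex, so closed surfaces rasterize watertight with no
random ray directions.  Triangles projecting to zero area contribute no
crossing.  Voxels inside no surface stay background; a voxel inside
several tags (possible only through numerical degeneracy, and structurally
excluded at exact shared interfaces) goes to the tag with the nearest
surface, ties to the lowest label.  Output bounds default to the source
image bounds padded by one target voxel.

## Meshing

Because the image has already been upsampled to modeling resolution, each
foreground voxel is split into the six Kuhn tetrahedra of its cell.  The
split is translation invariant, so shared cube facets receive the same
diagonal in both neighbouring voxels and the mesh conforms globally; all
six tets are positively oriented by construction.  Element tags equal the
source voxel label, so per-tag mesh volume equals voxel count × voxel
volume exactly and boundary faces of each tag form closed surfaces.  An
optional boundary-snapping pass pulls surface nodes towards the tagged
surface under the same half-voxel cap, reverting any move that would
invert an adjacent element.  Octree-style local refinement and true
surface-fitted boundaries are out of scope; the CARP/VTU readers and
writers allow substituting an external boundary-fitted mesh.

## Anatomical surface derivation

`tag_boundary` returns the faces incident to exactly one element of a tag
selection (the topological boundary); the background surface is obtained
as the boundary of all foreground.  Derived surfaces: lv_endo = myocardium
∩ LV-pool surfaces; rv_endo = myocardium ∩ RV-pool (this includes the
septal faces where the RV pool abuts LV myocardium, so the derived sets
partition the full myocardial boundary); per-ventricle epicardium =
ventricle surface ∩ background surface, total epicardium = union of the
two; base = myocardium–background faces within a z-band below the topmost
boundary node (essentially zero by default for a flat cut; the pipeline
widens the band to 0.5·source + 1.5·target spacing because smoothing plus
re-rasterization staircases the cut within the half-voxel cap); apex = the
epicardial node with minimal z, ties broken by lowest node id.

## Fiber architecture

Four harmonic potentials are solved on the myocardium with linear
tetrahedral finite elements (Jacobi-preconditioned CG to relative residual
1e-10, direct sparse fallback): φ_lv, φ_rv, φ_epi (one surface at 1, the
other two at 0) and an apicobasal ψ (base 1, apex 0).  Node sets are made
disjoint with endocardium-over-epicardium precedence: where a blood pool
reaches the background within one voxel (crescent seam, base rim) a node
can lie on several derived surfaces, and its endocardial identity governs
the transmural fields.  On the lattice meshes the stiffness matrix is an
M-matrix, so the discrete maximum principle holds; violations on user
meshes raise a warning, never silent acceptance.

Per element (gradients are constant on linear tets; nodal averaging is
deliberately not used, to avoid smearing across the LV/RV junction):
per-ventricle transmural coordinates d_v = φ_epi/(φ_epi + φ_v) define
transmural directions ∇d_v; the frame is (c, l, t) with t = ∇d_v
normalized, l = ∇ψ orthogonalized against t, c = l × t.  The frame is
rotated about t by the helix angle α(d_v) = α_endo(1−d_v) + α_epi d_v and
about the fiber axis by the sheet angle β(d_v) (defaults +60°/−60° and
0°/0°; the conventional values for this rule family, config-exposed and
never hard-coded in tests of the mechanics).  LV and RV frames are blended
by bidirectional quaternion slerp (candidates {1, i, j, k}·q with the
double-cover sign folded in; the candidate closest to the partner frame is
interpolated) weighted by w = φ_rv/(φ_lv + φ_rv); a linear per-axis blend
with re-orthonormalization is available as a fallback.

Numerical safeguards: elements whose nodes are all Dirichlet have exactly
zero field gradients and inherit the average gradient of face-adjacent
elements (iterated; a component that never fills signals genuinely
disconnected boundary sets and raises).  One face-neighbour averaging pass
over the element gradient fields (config: `gradient_smoothing_passes`,
default 1) damps gradient-direction noise in the first element layer of
the staircased Dirichlet boundary.  Where ∇ψ is collinear with the
transmural direction (apex pole) a fixed reference axis substitutes the
longitudinal direction; the helix frame is genuinely singular on the apex
axis — a property of every rule of this family — so fiber continuity is
quantified by quantile (99 % of face-adjacent element pairs within 45°)
rather than a maximum.  Helix angles are reported folded into (−90°, 90°]
because the fiber is a direction, not a vector.

The rule represents only bulk ventricular fiber architecture: no
trabeculation or papillary rules, no atria, no diffusion-MRI ingestion.

## Pipeline

One config object (YAML-expressible) drives phantom-or-file input, all
stage parameters, the output directory and the single seed; artifacts are
written per stage with a manifest (config, config hash, versions, timings,
mesh quality).  After rasterization, satellite connected components of
each tag are removed (config-exposed, default on): boundary noise can
spawn voxel islands that carry no Dirichlet information for the fiber
rule, and island removal is standard segmentation post-processing.  All
randomness flows from the config seed; reruns with identical config and
seed produce byte-identical CARP outputs (fixed-format text writers, no
unordered iteration anywhere in the geometry path).

## Test problem sizes

Verification problems were sized to run comfortably on one CPU: smoothing
verification on ≤40-vertex toy surfaces against the dense oracle; the
clinical-scale smoothing bound on the full-size phantom (~195k vertices);
Laplace verification on a 10-voxel slab (exact) and spherical annulus
r=10–15 mm at h=2 and 1 mm (observed error ratio ≈6.6 under refinement,
i.e. at least second order); the fiber rule on a cylindrical annulus
r=10–15 mm, height 20 mm at 1 mm (48k tets); the end-to-end determinism
check on the half-size phantom re-rasterized at 0.5 mm (~1.5M tets).

## Known limitations

- Voxel-face (staircase at modeling resolution) mesh boundaries rather
  than surface-snapped ones; the smoothing happens on the surface before
  rasterization, so the staircase amplitude is one *target* voxel.
- Axis-aligned images only; no oblique orientation support.
- The helix-angle transmural profile follows the harmonic coordinate,
  which is logarithmic (not linear) in radius on thick annuli; regression
  against the geometric coordinate therefore recovers the configured slope
  only to within a few percent by construction.
- Surface areas of midpoint-vertex extractions carry a constant ~1.27
  lattice factor; use them comparatively, not absolutely.
- The phantom's flat base and two-ellipsoid fusion are idealized; valve
  plane anatomy, four-chamber topology and trabeculation are out of scope.
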