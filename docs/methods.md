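# Methods

`archflow` models pulsatile blood flow through embryonic aortic-arch
vasculature and quantifies the geometry and shape variation of such
anatomies. This note records the governing model, the numerical choices,
what the synthetic phantoms do and do not emulate, and the known
limitations.

## Flow model

Blood is treated as an incompressible Newtonian fluid,

    ρ ∂u/∂t + ρ (u·∇)u + ∇p − μ ∇²u = f,        ∇·u = 0,

with density ρ = 1060 kg·m⁻³ and dynamic viscosity μ = 3.71×10⁻³ Pa·s by
default (embryonic blood at the modeled stage carries few erythrocytes
and behaves effectively Newtonian; both constants are configurable).
Walls are rigid and impermeable with no-slip velocity. Driving pressures
are prescribed at the inlet (outflow-tract) and outlet (dorsal-aorta,
plus optional cranial) caps as T-periodic signals — a sinusoid by default
(no canonical embryonic waveform table exists at this stage; measured
waveforms can be supplied as CSV samples). The cardiac period defaults to
T = 0.4 s and is configurable. The body force f defaults to zero.

At the scales modeled (vessel radii of tens of micrometres, Reynolds
numbers of order 0.1–1, Womersley number α = R√(ωρ/μ) ≈ 0.1) the flow is
laminar and quasi-steady: the instantaneous velocity field tracks the
instantaneous pressure drop. The verification suite checks this limit
explicitly against the closed-form Poiseuille solution.

## Discretization

* **Elements.** Taylor–Hood P2–P1 tetrahedra (quadratic velocity, linear
  pressure): inf-sup (LBB) stable, so no pressure stabilization is used.
  Cells are straight-edged; all geometry maps are affine.
* **Pressure boundaries.** Imposed weakly as the natural boundary term of
  the gradient-form weak formulation, (μ ∂u/∂n − p n) = −p_bc n. This
  "do-nothing" traction form is exact for fully developed flow and
  permits flow reversal.
* **Time stepping.** Backward Euler at Δt = 0.01 s for four cardiac
  cycles (defaults). The nonlinear convective term ρ(u·∇)u is evaluated
  **explicitly** at the previous step and carried on the right-hand side,
  so the saddle-point matrix is constant in time and factorized once per
  run. At cell Péclet numbers ≪ 1 this is unconditionally benign; for
  stiffer regimes a semi-implicit Oseen variant and Picard iteration are
  available (`TimeSteppingSpec.convection`). The convective right-hand
  side uses an 8-point (degree-3) quadrature; the slight
  under-integration of this degree-5 integrand is far below the explicit
  time-lag error of the same term.
* **Linear solver.** Monolithic sparse LU (SuperLU, symmetric-mode
  minimum-degree ordering, diagonal pivot threshold 0.01) with one step
  of iterative refinement; solves are rejected above a relative residual
  of 10⁻⁸. Pressure dofs whose continuity rows vanish under the no-slip
  constraints (one-cell-thick passages on marginal meshes) and pressure
  levels of flow chambers with no path of free velocity dofs to a cap are
  pinned to zero; both conditions are detected structurally and warned
  about.
* **Units.** Meshes carry millimetres; the solver converts to SI on
  load. Velocities are m/s, pressures and WSS Pa (1 Pa = 10 dyn/cm²).
* **Start-up.** Simulations start from rest; reported metrics use the
  final cycle, by which the start-up transient (viscous time scale
  R²ρ/μ ≈ 1 ms ≪ T) has decayed.

Verification: with the solution quadratic in the cross-stream plane, P2
velocity represents Poiseuille flow exactly in the interior; the
remaining error is the polygonal approximation of the circular wall,
which converges at second order. Measured at cross-stream resolution
h = R/6: velocity L2 error ≈ 0.8 %, flow-rate error ≈ 1 %, wall-shear
error ≈ 0.3 %; the observed order over the series h = R/3, R/4, R/6 is
≈ 2.05. For straight tubes the generator decouples axial spacing from
the cross-stream h, since the solution varies linearly axially.

## Wall shear stress

WSS is the tangential traction magnitude |t − (t·n)n| with
t = μ(∇u + ∇uᵀ)·n, evaluated from the discrete velocity gradient of the
parent cell — the full symmetric gradient, which is exact for the
discrete solution and robust on curved walls. The primary representation
is facet-wise: within a straight facet ∇u is linear, and the facet value
is the 3-point edge-midpoint average of the traction magnitude (exact
for quadratic integrands). Regional summaries are area-weighted. "Peak
flow" and "accelerating flow" are defined operationally on the final
cycle as the argmax of the inlet flux and of its time derivative.

## Streamlines

Streamlines are integral curves of a frozen velocity snapshot,
integrated with classical RK4 on the arc-length-normalized field
dx/ds = u/|u| (uniform geometric resolution independent of speed;
stagnation tolerance 10⁻⁶ × the seed-point peak speed). Seeding uses a
sunflower-spiral point set on a cross-section plane, filtered to strictly
interior points. Each streamline is labeled by the arch region holding
the majority of its arc length. Order preservation between an
outflow-tract plane and a dorsal-aorta plane is scored two ways: the
Kendall rank correlation of the per-streamline lateral coordinates, and
the fraction of branch-adjacency relations (neighboring per-branch
centroids in the lateral ordering) preserved downstream. These two
scores operationalize the qualitative notion of "maintained streamline
order" in laminar arch flow.

## Vessel geometry

Centerlines are paths of maximal inscribed spheres (MIS): Dijkstra on
the mesh vertex graph with edge weight length/d² (d = exact distance to
the wall triangulation), followed by gradient-ascent medialization
normal to the path (which removes junction corner-cutting) and light
smoothing; radii are re-evaluated exactly at the final points. Local
diameter is 2×MIS radius. Tortuosity is arc/chord − 1. Curvature is the
mean three-point Menger curvature of an arc-length resampling of the
path (resampling suppresses mesh-scale zig-zag; the value remains
smoothing-dependent and carries a wide tolerance). Cross-section
ellipticity is the √(eigenvalue-ratio) of the second moments of mesh
vertices in a thin slab normal to the centerline. Branch volumes are
exact sums of cell volumes per region tag. Per-branch measurements are
compared across factors (arch pair, side) with one-way ANOVA and Tukey
HSD, starred at 0.05/0.01/0.001.

## Morphometrics

Generalized Procrustes analysis iterates centering, optional unit-size
scaling, and proper orthogonal alignment (SVD with reflections
disallowed — left/right arch chirality is anatomically meaningful) to a
converged mean (relative mean change < 10⁻¹⁰ or 100 iterations). The
default mode preserves centroid sizes (Boas coordinates), appropriate
when absolute growth matters; results record which mode was used. PCA of
the residual matrix uses an SVD (equivalent to the covariance
eigendecomposition) with a deterministic sign convention. Outliers are
flagged by median/MAD-standardized Euclidean distance in the leading PC
scores (threshold 3.5; MAD = 0 falls back to the SD with a warning).
Because alignment quotients out similarity transforms, planted
generator modes are compared to fitted loadings only after projecting
out translations, infinitesimal rotations (and scale, when applicable) —
`project_out_similarity`.

## Synthetic phantoms

The phantom module generates the study geometries:

* **Tubes** (straight / elliptical / stenosed) are triangulated exactly
  from their parametric description and are the quantitative
  verification geometry. Stenoses use a C1 cosine radial taper
  r(s) = R(1 − severity·w(s)), avoiding the spurious WSS singularities a
  step constriction would create.
* **Arch phantoms** emulate the three-bilateral-pair stage: a gently
  curved outflow tract along the cranio-caudal axis, arch pairs as
  circular arcs in parasagittal planes mirrored about the midsagittal
  plane, elliptical arch cross-sections (squashed along the plane
  normal), a dorsal aorta collecting the arches, and optional cranial
  outlets from the AA II apices. The default proportions follow the
  reported anatomical pattern at this stage — AA III shortest and
  widest, AA IV narrowest — with radii in the order-of-magnitude range
  of reported arch diameters (tenths of a millimetre): OFT 0.12 mm, DA
  0.10 mm, AA II/III/IV 0.068/0.080/0.060 mm, arch ellipticity 0.85.
  Surfaces are the zero level set of a union of tube signed-distance
  fields (distance to the nearest axis point minus the radius *there*,
  so steep stenoses are not washed out by neighboring wide segments),
  extracted by marching cubes — watertight and manifold by construction
  for any non-self-intersecting parameter set.
* **Landmark cohorts**: 275 pseudolandmarks along the branch centerlines
  by default, perturbed by orthonormalized smooth variation modes with
  Gaussian scores plus isotropic noise; "missing-arch" outliers collapse
  one arch's landmarks onto the adjacent arch path, preserving the
  landmark count that GPA requires.

What the phantoms do **not** emulate: image-derived surface texture and
segmentation noise, non-circular centerline meanders, wall compliance,
and the junction geometry of real tissue. Passing pattern tests on
phantoms therefore demonstrates that the pipeline recovers constructed
ground truth and reproduces the qualitative hemodynamic logic (stenosis
→ elevated WSS; laminar order preservation with the outer-pair split;
shortest/widest pair → highest mean WSS under a common driving
pressure), not that any specific embryo exhibits these numbers.

On the WSS pattern: for parallel branches under a common pressure drop,
Poiseuille traction is τ = Δp·r/(2l) — higher in *wider and shorter*
branches (flow redistributes as r⁴). The phantom reproduces the observed
"highest mean WSS in AA III" precisely because AA III is built shortest
and widest; a narrowed branch under pressure-driven flow receives less
flow and *lower* wall shear. The fixed-flow intuition τ ∝ r⁻³ applies
only when a branch's flow is externally imposed, as in the
stenosed-outflow-tract case where the throat carries the entire cardiac
output.

## Meshing

Structured tube meshes sweep a Delaunay-triangulated disk along the axis
(prisms split into tetrahedra with the smallest-global-index diagonal
rule, which guarantees conforming faces) and are promoted to P2 by
mid-edge insertion. Arbitrary watertight surfaces are filled by Delaunay
triangulation of jittered interior lattice points plus the surface
vertices, keeping cells whose centroid lies inside (with a slack of
0.35h against the implicit surface, since the triangulated surface
interpolates it linearly); stray disconnected fragments are discarded,
boundary slivers (radius-ratio > 25 *and* near-zero volume) are peeled,
and unreferenced vertices are compacted. Boundary facets inherit the tag
of the nearest input-surface triangle. This generic path trades boundary
smoothness for robustness: phantom walls are jagged at the grid pitch,
which perturbs local WSS maxima but not regional means or flow
partitioning. Quantitative oracles therefore always use the structured
generator.

## Problem sizes and defaults

The bundled verification runs use: Poiseuille tube at h = R/6 (~5.5k P2
cells), refinement series h = R/3…R/6, pulsatile tube at h = R/4, and
arch phantoms at surface pitch 0.03 mm / volume h = 0.035 mm (~25k P2
cells, ~125k unknowns), four cycles at Δt = 0.01 s. These sizes resolve
every feature the assertions test while keeping a full verification
sweep at desk scale; the same code paths run unchanged on finer meshes
(e.g. the ≥100k-element, 0.009 mm-spacing regime of image-derived
anatomies) at correspondingly higher cost.

## Known limitations

* Rigid walls; no fluid–structure interaction or moving outflow tract.
* Newtonian rheology only.
* No turbulence modeling (irrelevant at Re ≤ 10) and no uncertainty
  quantification / parameter sensitivity machinery.
* The Delaunay-filter mesher is robust but low-order accurate at curved
  boundaries; it is not a quality mesher for production CFD on scanned
  anatomies.
* Landmark correspondence across specimens is assumed given (the FCSV
  contract); no automatic landmark transfer is provided.
* WSS is reported as instantaneous magnitudes (mean/max/peak); no
  oscillatory shear index or time-averaged WSS derivatives.
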