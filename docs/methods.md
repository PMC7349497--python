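# Methods

## Scope and units

`mealscan` post-processes partial triangle-mesh scans of food into
watertight per-item volumes and consumed-nutrient estimates. All mesh
coordinates are interpreted as centimeters and volumes as cm³ (OBJ
carries no unit; desk-scale food scanning makes cm the natural choice),
weights as grams, densities as g/cm³.

## Mesh handling

Meshes are indexed vertex/face arrays with counter-clockwise winding
viewed from outside. Scanner exports routinely duplicate vertices along
seams, so topological analysis is preceded by a cleaning pass: vertices
within 1e-6 cm are welded (grid rounding on the original coordinates,
first-occurrence order preserved so cleaning an already-clean mesh is
the identity) and faces that become degenerate or fall below 1e-10 cm²
are dropped. A boundary edge is an edge used by exactly one face; a
mesh is watertight when it is edge-manifold with zero boundary edges.

The OBJ reader interprets only `v` and `f` records (fan-triangulating
polygons) and reports malformed content with 1-based line numbers;
normals, textures and materials are ignored because the pipeline is
geometry-only. The writer emits full `repr` precision so a
write/read cycle is a fixed point on faces and stable to well below
1e-6 cm on coordinates.

## Hole identification

Boundary half-edges are traversed in the direction that puts the hole
on the left, i.e. counter-clockwise around the loop's Newell (area)
normal; filling triangles wound in traversal order then match the mesh
orientation. A vertex shared by two boundary cycles (a pinch, e.g.
when a puncture grazes a cone apex) starts several boundary half-edges;
traversal consumes them with a deterministic smallest-successor rule
and a step bound so malformed boundaries fail loudly instead of
looping.

The front angle θᵢ at a boundary vertex is the 3D angle between its two
boundary edge vectors, measured on the hole side. Reflex classification
(θ > 180°) is genuinely ambiguous on curved boundaries; two tests are
combined:

- *wedge complement*: the hole wedge plus the summed corner angles of
  the faces currently incident to the vertex should total ≈ 360°; when
  θ and 360° − θ differ on that score by more than 45° the better fit
  wins. This is what recognises a near-full-turn hole angle at a cone
  apex whose edges subtend only a few 3D degrees.
- otherwise the side test against the loop normal decides (the sign of
  (e_fwd × e_bwd)·n̂). Angular-deficit corners (e.g. a cube corner,
  where both hypotheses miss 360° by the same amount) land here.

## Advancing-front filling

Each iteration advances the front vertex with the globally smallest θ
(ties broken by lowest vertex index, for reproducibility): direct
connection at θ ≤ 75°, one bisector vertex at 75° < θ ≤ 135°, two
trisector vertices above. New vertices are placed in the plane of the
two boundary edges at the mean of their lengths; for near-collinear
edges the rotation axis is stabilised with the loop normal. Candidates
within ε of an existing front vertex are replaced by it, choosing among
multiple hits the vertex whose fan triangles are closest to equilateral
(quality 4√3·A/Σl²); a merge that would put a third face on an existing
edge is disallowed. When a merge reconnects the front to a non-adjacent
vertex the front cycle becomes non-simple and is split at the repeated
vertex into sub-loops, each filled in turn. Loops reduced to three
vertices are closed outright.

The default merge radius is ε = 0.5 × (mean boundary-edge length of the
loop), exposed as `epsilon_factor` in `FillConfig`; larger values
simplify the patch at the cost of geometric fidelity, and the patch
vertex count is non-increasing in ε on a fixed hole.

Two guards make the front robust on real degradations:

- a direct connection whose closing edge already carries two faces
  (the surface closes across, as at a pendant apex) is skipped in the
  selection, and
- if the front stops converging — iteration budget of 10 × loop size
  exceeded, or the front grows past twice its original size, which
  strongly reflex or misclassified regions can cause — the remaining
  loops are closed by minimum-angle ear clipping, which terminates
  unconditionally. This fallback trades patch quality for guaranteed
  watertightness and fires only on pathological fronts.

Multiple holes are processed largest boundary first; vertices away
from a patch are never touched (the fill is strictly local and
bit-preserving outside the hole).

## Harmonic refinement

Interior (newly created) patch vertices are repositioned by solving the
discrete Laplace equation with cotangent weights,
Σ_{vⱼ∈Nᵢ} ωᵢⱼ(f(vⱼ) − f(vᵢ)) = 0 with ωᵢⱼ = cot αᵢⱼ + cot βᵢⱼ, once per
coordinate, boundary and original mesh fixed — the minimiser of the
discrete Dirichlet energy of the patch. Weights are assembled from the
patch triangles (every triangle incident to a free vertex is a patch
triangle); angles below 1e-4 rad are clamped and cotangents clipped to
±1e6 so skinny triangles cannot destabilise the solve
(`scipy.sparse.linalg.spsolve`). Because constants solve the same
system, planar hole boundaries are reproduced exactly: planar holes are
filled coplanar. The same property is the method's known bias: over a
strongly curved hole (a missing dome) the membrane-like patch sags
toward the boundary ring instead of bulging — the fill under-estimates
convex volume. This is reported, not corrected; curvature-aware
refinement is out of scope.

## Volumetry

The enclosed volume of a watertight mesh is the divergence-theorem sum
V = |Σ_faces det(a, b, c)/6|, exact for polyhedra and invariant under
rigid motion. Because advancing-front patches can locally flip winding,
orientation is first repaired by propagating a consistent winding
across each connected component (breadth-first over shared edges) and
taking the magnitude per component, which also makes several disjoint
solids in one mesh sum correctly. Non-watertight input is rejected with
the boundary-edge count.

The independent oracle voxelises the bounding box at a given pitch and
counts voxel centers whose vertical ray crosses the surface an odd
number of times. Each axis of the grid carries a different irrational
offset (pitch×(√2−1), (√3−1), (√5−2)) so rays avoid mesh vertices,
edges and diagonal seams — equal offsets would cancel along 45° seams
and silently drop whole columns. At 0.05 cm pitch the oracle agrees
with the analytic sum to well under 2% on all fixtures.

## Segmentation

Plate removal replaces an interactive mesh-editor step: RANSAC plane
fitting (default 200 draws, inlier tolerance 0.3 cm, minimum supporting
fraction 0.2, fixed RNG seed) followed by an SVD refit on the inliers;
faces with all three vertices within tolerance become the plate. Item
splitting likewise replaces interactive selection with one 3D seed
point per item: faces go to the seed with the smallest geodesic
distance over the face-adjacency graph (edge weight: centroid
distance), with adjacency cut where the dihedral angle between
neighbouring faces exceeds `crease_angle` (default 50°) — the junction
between touching food items is such a crease. Faces unreachable from
every seed fall back to the Euclidean-nearest seed.

## Nutrition accounting

W = V·D converts leftover volume to weight; CN(i) = W·ND_g(i) converts
weight to per-component amounts (calories in kcal/g, carbohydrate,
protein, sugar, fat as mass fractions g/g, validated ≤ 1); CoN(i) =
RN(i) − CN(i) subtracts the leftover from the kitchen-reported serving.
When a meal has several items their leftover nutrients are summed
before the subtraction (the kitchen reports the meal as a whole). A
component whose calculated leftover exceeds the serving keeps its
negative consumed value and is flagged — it signals a volume
over-estimate or a wrong density, and silently clamping would hide
that. Density tables are plain CSV so any source can be plugged in;
the packaged table is a synthetic example with plausible values, not an
extract of any proprietary database. Per-100 g sources divide by 100.

## Synthetic scan generator

The generator emulates what desk-scale depth scanning does to a closed
surface: Gaussian vertex displacement along vertex normals (sensor
noise; normal direction is the proxy for the view ray at desk scale)
and punched-out face neighbourhoods (blind spots, the unseen bottom of
an item, contact seams). Ground truth stays noise-free; the degraded
mesh is a strict face-subset of the noised copy, and every draw comes
from one integer seed with no global RNG state. Primitives: the
12-triangle cube, an inscribed fan cone, and food-like blobs (deformed
icospheres: polar-dimpled "apple", bent flattened "croissant", squashed
"mound") with a seeded low-frequency radial perturbation.

The fixed evaluation suite holds twelve scenarios — cubes with edges
5–10 cm and cones with radii 2–4 cm and heights 4–8 cm, each subdivided
for realistic face counts, degraded by one puncture covering 10% of the
surface area and 0.03 cm surface noise. These sizes match single food
items on a tray; the puncture fraction sits below the regime where a
hole stops being local. What the generator does **not** emulate:
view-dependent occlusion patterns, correlated (non-Gaussian) sensor
error, specular dropout, or the ragged boundaries of real contact
seams. Passing the suite therefore demonstrates the pipeline's
geometric correctness and robustness to moderate, uncorrelated
degradation — not field accuracy on real scans.

## Benchmark trials

The packaged 13-trial table records, per meal, the control measurement
(weighing scale) and the grams estimated by three methods: an automated
24-hour recall interview, the MyFitnessPal app, and the 3D-scanner
pipeline. Summary statistics per method use only the trials where the
method reported: total absolute error; that total divided by the total
actual grams of the same trials (×100); and the population standard
deviation (divide by n) of the per-trial absolute errors — the only
definitions consistent with the recorded scanner and MyFitnessPal
summaries. The recall method's recorded summary (389 g / 51% / 34 g)
is *not* derivable from its own per-trial column by any single rule
(the column's absolute errors total 504 g); it is carried as metadata,
printed with an explicit "as printed, not recomputed" marker, and never
asserted. No exclusion rule is guessed.

## Numerical choices and degenerate inputs

- θ ties broken by lowest vertex index; hole processing order is
  largest loop first; all randomness (RANSAC, generator) is behind
  explicit seeds — identical inputs give byte-identical outputs.
- Weld tolerance 1e-6 cm; degenerate-face area threshold 1e-10 cm²;
  cotangent clamp 1e6 with 1e-4 rad angle floor; boundary loops shorter
  than 3 vertices are rejected.
- Empty meshes write a header-only OBJ; a bare-plane scan segments to
  plate-only with an empty item list; a scan with no supporting plane
  raises a "no plate found" error rather than guessing.

## Limitations

- The membrane patch under-estimates strongly curved missing regions
  (missing dome ⇒ flattened fill); errors of several percent on a
  puncture spanning a cube corner or cone flank are expected and
  bounded by the evaluation suite, not eliminated.
- Non-self-intersection of patches is guaranteed only for convex
  planar holes (and checked there); concave or non-planar holes can in
  principle self-intersect and are only reported watertight.
- Item splitting needs one seed per item; automatic food segmentation
  and recognition are out of scope.
- The voxel oracle is O(columns × triangles) and intended for
  validation at moderate pitch, not production use.
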