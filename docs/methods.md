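# Methods

This note records the modelling assumptions, parameter defaults,
numerical choices and known limitations behind `hexcart`. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and model

The package targets *laminar* tissues: a cartilage layer bounded by a
bone-side and a joint-side surface, geometrically close to a patch of a
plane or cylinder. Every cartilage mesh is produced by swept-extrusion:
paired rectangular grids of ray hits on the two surfaces, connected
through the thickness into one layer of 8-node hexahedra, then
subdivided in-plane and depth-wise. Bones enter downstream simulations
as rigid shells, so they are meshed as triangular surfaces only. The
pipeline makes no attempt at general-purpose all-hex meshing of
non-laminar solids, and menisci are out of scope.

## Synthetic phantoms

Real segmented knee MRI is access-restricted, so the generator builds
stand-ins with exact implicit geometry:

* **slab** — flat or cylindrically bent cartilage plate of constant
  thickness over a bone slab; the canonical small test case.
* **femoral** — condylar cylinder (default R = 30 mm, width 25 mm) with
  a cartilage shell wrapped over 120°; exercises the radial-fan sweep.
* **tibial** — flat plateau with two elliptical compartments carrying
  independent medial/lateral labels; exercises planar projection and
  the sector/rectilinear grids.
* **patellar** — single flat elliptical patch; exercises the
  quasi-planar degeneration of the condylar sweep.

Holes are right cylinders through the full cartilage depth, specified
in the developed (unrolled) patch coordinates — the shape of focal
full-thickness cartilage loss. Label volumes sample the implicit
occupancy at cell centres (default 0.5 mm isotropic voxels, default
tissue-code table in `hexcart.volume.DEFAULT_TISSUE_CODES`; image
formats carry no tissue names, so a JSON sidecar preserves the map).
Ground-truth surfaces are extracted from the same occupancy by marching
cubes at the voxel spacing, after a σ = 0.8-voxel Gaussian
anti-aliasing filter (see below), so they are closed 2-manifolds for
arbitrary hole layouts while staying within a voxel diagonal of the
analytic geometry; the recorded ground-truth parameters (thickness,
radii, hole centres) are exact.

What the phantoms do **not** emulate: population shape variation,
osteophytes, MR intensity artifacts, segmentation noise beyond what
morphological closing is meant to remove, and menisci. Passing tests
therefore demonstrate algorithmic correctness and robustness on
idealized laminar geometry, not clinical segmentation performance.

## Reconstruction

Per tissue: morphological closing (cubic kernel, 5 voxels for
cartilage, 3 for bone — the kernel shape is not dictated by the
procedure the pipeline follows; cubic was chosen and is trivial to
swap), marching cubes (topology-consistent Lewiner variant) at the
0.5 iso-level, retention of the largest enclosed volume (closed
components ranked by divergence-theorem volume, open artifacts by
area), quadric edge-collapse decimation to an 80% triangle reduction,
nine iterations of umbrella-weight Laplacian smoothing (λ = 1, boundary
vertices free), and repair — full (degenerate faces, duplicates,
normals, hole filling, watertightness enforced) for bones,
normals-only for cartilage so physiological holes survive.

Marching cubes on a raw 0/1 mask produces lattice faceting that
inflates surface area by ~10% without moving the surface; a symmetric
Gaussian pre-filter of σ = 0.8 voxels removes the faceting while
shifting the 0.5-level surface by well under a tenth of a voxel. Set
`antialias_sigma=0` for raw binary extraction.

## Bone remeshing

Centroidal Voronoi clustering: the input is refined to ≥ 30 samples
per cluster, faces are partitioned into *connected* clusters by
multi-source region growing (seeded watershed keyed on distance to the
cluster centroid) iterated Lloyd-style with farthest-point
initialization, and the cluster dual is triangulated by walking the
ordered face ring of each fine vertex. Connectivity-constrained
clustering matters: unconstrained (k-means) clusters bridge thin
plates such as a tibial bone slab and yield non-manifold duals.

Cluster count: an equilateral tiling of area *A* at edge *a* has
`2A/(√3 a²)` vertices, and clusters become vertices, so
`n_clusters = round(2A/(√3·target²))` makes the mean output edge track
the target (the r = 20 mm sphere at the default 3 mm target lands
within a few percent; the acceptance script recomputes this). The
sampling density doubles (deterministically) on the rare non-manifold
dual, and the whole procedure is reproducible from one seed.

## Hexahedral sweep

* **Scaled Jacobian.** `SJ = min₈ det[ê₁ ê₂ ê₃]` over unit-normalized
  corner edge triples, corner ordering chosen so a cube scores +1 at
  every corner (bottom quad counter-clockwise, then top). SJ is
  invariant to rigid motion and uniform scaling; ≤ 0 flags degenerate
  or inverted elements. An independent brute-force corner-determinant
  oracle in the tests agrees to 10⁻¹⁰.
* **Ray layouts.** Femoral/patellar: the cylinder axis direction is the
  null direction of the face-normal covariance; axis position and
  radius come from a Kasa circle fit of the projected vertices. The
  fit is accepted only if the shell is a thin annulus around the axis
  (radial spread < half the mean radius); otherwise — flat patches —
  the axis is placed 500 mm beneath the patch on the bone side, and the
  fan degrades smoothly to quasi-parallel rays. Tibial: projection
  along the plateau normal with back faces discarded; the default
  "sectors" grid maps the unit square onto the ellipse inscribed in the
  0.9-scaled bounding box of the footprint (grid lines fan radially
  toward the rim without a polar seam or pole — the working
  interpretation of a radial-sector interior grid), with a rectilinear
  grid on the unscaled box as the simplified fallback.
* **Hit classification.** Along each ray, entering/exiting crossings
  (sign of normal·direction) give the bone-side and joint-side hits;
  near-duplicate hits (|Δt| < 10⁻⁷) from shared vertices are collapsed;
  hit pairs whose depth falls outside 0.25–4× the median are rejected
  as side-wall clips. If fewer than 60% of the rays that touch the
  surface produce valid pairs, the strategy signals failure.
* **Grid pitch** is twice the 1 mm target edge, so the single 2×2
  in-plane subdivision lands on target.
* **Degenerate taxonomy.** Cells with exactly three valid corners enter
  as six-node wedges (missing corner collapsed onto its CCW-next valid
  neighbour). Classification over the 4-adjacency graph of wedge
  cells: isolated wedge with ≥ 2 full-cell neighbours → *corner*;
  isolated otherwise → *peak*; adjacent pair whose two distinct missing
  corners are both grid-adjacent to one common valid node on the shared
  cell edge (so both collapses target the same node and the repeated
  element-local indices coincide) → *step*; any other adjacent pair,
  including both cells missing the same shared node → *mirror*; a
  three-chain → *stair*; anything larger raises a classification error
  listing the element ids (never silent). Repairs: corner →
  reconstruct the missing grid node by linear extrapolation of
  neighbouring ray hits (node creation, re-projected to the surface);
  peak/step/mirror/stair → delete the 1/2/2/3 offending elements. A
  step "merge" into a single kite-shaped hex was prototyped and
  rejected: it manufactures a flat 180° corner (SJ = 0) that the
  optimizer must then rescue.
* **Sliver trimming.** Ragged sweep boundaries can leave cells no node
  motion can fix (in-plane slivers, pinch vertices where the boundary
  touches itself). Boundary-touching elements with SJ < 0.15, and the
  worst element at any pinched rim vertex, are deleted before
  optimization; if optimization stalls, boundary-touching below-target
  elements may be trimmed and optimization retried. Interior
  below-target elements are never trimmed — they fail the stage.
* **Optimization.** Constrained Laplacian smoothing (interior nodes
  toward their quad-neighbour mean, rim nodes along the rim only,
  every move re-projected to the source surface) alternating with a
  targeted pass over the below-target elements and their 1-ring. An
  iteration is accepted only if the count of below-target elements does
  not increase (monotone acceptance); the step halves on rejection, and
  a hard `max_iterations = 200` guard turns any stall into a reported
  error rather than an unbounded loop.
* **Subdivision.** In-plane 2×2 with shared midpoint keying (conformity
  by construction, original corners untouched, new nodes re-projected);
  depth into four linearly spaced layers along each bone-joint node
  pair.
* **Fallback cascade** (cumulative, recorded in provenance): disable
  bone fusion → halve blend displacement → tibial rectilinear grid →
  perform the in-plane subdivision early (before stage-1 optimization).
  On the shipped phantoms the primary strategies succeed without
  fallbacks; the cascade is exercised in tests by forcing a sector-grid
  failure.

## Blending

Conventions: the *feature angle* of an edge is the angle between the
unit normals of its two faces (0° = coplanar, 90° = perpendicular), so
a blend ramp rising at slope θ from the joint surface makes a crease
feature angle of θ. The 35° enforcement minimum and the 30° joint-side
smoothing stop use this one convention.

Displacement budget per edge node = local depth / tan(45°); the
bone-side node stretches outward along the bone tangent by 80% of it,
the joint-side node compresses inward by 20%, which reproduces the 45°
ramp exactly on a flat slab. Directions come from the point normals of
the wall faces at the cartilage edge, projected into the local surface
tangent plane. With a bone mesh present, stretched bone-side nodes
snap to its nearest element surface unless that means travelling more
than 2× the local depth (such nodes stay unfused and feed the fusion
tier reported in provenance: *full*, *perimeter* — outer loop fused,
hole loops not — or *unfused*).

Feature-angle enforcement relaxes only the bone-side magnitudes of
nodes adjacent to violating creases, in decrements of 10% of the
initial magnitude; at zero relaxation the wall is vertical (crease
90°), so termination is guaranteed and levels are monotone
non-increasing. Fold-over at interior curves and holes is handled by
degree-3 Savitzky–Golay filtering of the displaced edge-loop
coordinates (window 7, the smallest symmetric window comfortably above
the degree; periodic padding along closed loops; cubic edge curves are
reproduced exactly), then global 10% magnitude reductions until the
triangulated faces of all rim-adjacent elements are intersection-free
(transversal crossings; coplanar overlap is not tested, which is
adequate for fold-over detection). Reaching zero magnitude with
intersections is an error that triggers the cascade.

Graduated smoothing: bone-side fronts at element depths 2→5, initial
iteration count `ceil(550·n_surf/(n_surf − n_front))` from quad-face
counts, capped at 2000 to bound runtime and halved at each advance;
joint side advances once with its full initial count, checked every 10
iterations against the 30° stop and the quality gates (blended-element
SJ > 0, interior SJ > 0.5 or no worse than the incoming mesh).
Cartilage edge nodes are pinned, and no node beyond the fifth edgewise
layer ever moves — blending is strictly a geometry operation on a
five-layer band; connectivity and counts are untouched.

## Attachment sites

Femur-driven registration: centroid + principal-axes pre-alignment
(four proper axis-flip candidates, lowest-residual kept), then ICP with
point-to-nearest-surface-point correspondences and a closed-form
similarity (Umeyama) update — 7-dof by default since template and
subjects differ in scale; rigid mode available. The same transform
carries all tissues. Sites and joint-axis landmarks map to the nearest
subject node in the template frame (ties broken by lowest node id) and
are reported at the node's original subject coordinates, which is
exactly the inverse transformation back to subject scale and position.

## Metrics

Surface deviation traces each predicted node to its nearest point on
the reference surface over element faces (not just vertices); nodes
whose ray deviates more than 20° from the area-weighted node normal
(measured against the undirected normal line) are excluded, and the
retained fraction is the percent nodal coverage. Summary statistics
are computed over included nodes only; the density estimate is a
Gaussian KDE with Scott bandwidth. The deviation is directional
(predicted → reference); swap the arguments for the reverse direction.
Dice is the standard overlap `2|A∩B|/(|A|+|B|)`; min–max RMS reports
the RMS series difference and its percentage of the *reference*
series' range, making the percentage invariant to affine rescaling
applied to both series.

## Pipeline and IO

The orchestrator isolates per-tissue failures, records fallbacks,
layer-wise SJ summaries, the config hash and seed in a provenance JSON,
and keeps timings in a separate log so mesh outputs are byte-identical
across runs; worker pools (3 bones / 4 cartilages by default) run the
same pure functions as the serial path, so pooled and serial outputs
are identical. Configuration is schema-validated with unknown keys
rejected. Formats: NIfTI/NRRD/MetaImage labels, STL/PLY/VTK/VTU
meshes (the VTK/VTU readers and writers are self-contained ASCII
implementations), and an Abaqus-INP-dialect deck with C3D8 cartilage
continua, R3D3 rigid bone shells and one node set per mapped site,
written at full double precision for exact round trips.

## Problem sizes

The shipped phantoms are sized for interactive work: the condyle
phantom meshes into ~5.5k hexes (~1.4k single-layer elements), the
tibial compartments into ~1.6k each, and the acceptance script's
sphere remesh has ~1.3k triangles; the full test suite and the
acceptance script each complete in minutes on one CPU. All stages
scale to denser grids by lowering `target_edge_mm` and the phantom
voxel spacing.

## Known limitations

* The quadric decimator is pure Python; reconstructing very large
  bones (hundreds of thousands of marching-cubes triangles, e.g. a
  full femur at 0.5 mm voxels) takes minutes. Use coarser voxels or a
  lower decimation fraction when that matters.
* Voronoi-clustering remeshing assumes features larger than the target
  edge; plates thinner than ~1.3× the target lose rim volume to
  element rounding.
* The sector grid's square-to-ellipse mapping shears cells near the
  four mapped corners; the optimizer recovers SJ > 0.5 on the shipped
  plateaus, but extremely eccentric footprints may fall back to the
  rectilinear grid.
* Blending quality gates guarantee positive blended-element SJ, not a
  margin; heavily degraded geometries can end near zero.
* Coplanar face overlap is invisible to the blend intersection test.
* ICP needs the pre-alignment to land in the right basin; symmetric
  surfaces with near-equal principal axes may register into a flipped
  local minimum.
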