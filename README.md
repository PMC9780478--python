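# hexcart

Automated meshing of segmented knee tissues for finite-element contact
simulation: triangular rigid-body **bone** meshes and high-quality,
bone-blended **hexahedral cartilage** meshes, produced fully
automatically from multi-tissue segmentation label volumes.

Building subject-specific FE knee models has historically cost days of
hand meshing per joint, which rules out population-scale studies.
`hexcart` implements the whole image-to-mesh chain as a library plus a
CLI: surface reconstruction from label masks, isotropic bone remeshing,
swept-extrusion hexahedral cartilage meshing with degenerate-element
repair and quality optimization, cartilage-to-bone edge blending,
template-based placement of soft-tissue attachment sites, and the mesh
quality/comparison metrics used to evaluate such pipelines. Because
clinical imaging datasets are access-restricted, the package ships a
first-class synthetic phantom generator (laminar cartilage shells of
known thickness over flat or condylar bone, with through-holes
emulating focal cartilage loss) so every stage is testable at desk
scale with analytic ground truth.

## The core method

Cartilage is a thin laminar tissue bounded by a bone-side and a
joint-side surface. The mesher places two *matching rectangular grids*
of surface points by raytracing — radial fans swept along a fitted
condylar (cylinder) axis for femoral/patellar sites, planar projections
with a scaled-bounding-box sector grid (rectilinear fallback) for
tibial plateaus — and connects the paired grids through the thickness
into one layer of 8-node hexahedra. Boundary cells with only three
valid corners enter as six-node degenerates; they are classified into
*peaks, mirrors, steps (two elements), three-element stairs* and
internal *corners*, each with its own repair rule. Element quality is
measured by the scaled Jacobian

```
SJ(e) = min over the 8 corners c of det [ ê₁(c) ê₂(c) ê₃(c) ]
```

with êᵢ the unit-normalized edge vectors leaving corner *c*
(SJ = 1 for a cube, SJ ≤ 0 for a degenerate or inverted element). The
sheet is optimized to SJ ≥ 0 by constrained Laplacian smoothing with
re-projection onto the source surfaces, subdivided 2×2 in-plane,
optimized again to SJ > 0.5, then *blended* into the bone: edge nodes
are displaced into a 45° ramp (bone side carrying 80% of the
displacement and fusing to the bone mesh by nearest-surface search),
with feature-angle enforcement (≥ 35°), Savitzky–Golay smoothing of
the edge loops against fold-over, and graduated advancing-front
smoothing whose iteration count halves at each front. Finally the
depth is split into four linearly spaced element layers. A fallback
cascade (disable bone fusion → reduce blend displacement → simplified
tibial grid → early in-plane subdivision) makes the pipeline robust to
degraded geometries; every fallback that fires is recorded in the mesh
provenance.

Bones are meshed as rigid triangular shells by centroidal
Voronoi-clustering remeshing at a 3 mm target edge; attachment sites
are mapped from a template by similarity ICP plus nearest-neighbour
search; comparison metrics include surface deviation with percent
*nodal coverage* (rays deviating > 20° from the node normal are
excluded), Dice overlap, and min–max-normalized RMS differences.

## Worked example

```python
import hexcart as hc
from hexcart import hexsweep as hs

phantom = hc.make_joint_phantom("femoral", thickness_mm=2.0)
mesh = hc.mesh_cartilage(
    phantom.surfaces["femoral_cartilage"], "femoral", phantom.surfaces["femur"]
)
sj = mesh.scaled_jacobians()
print(f"elements: {len(mesh.hexes)}  layers: {mesh.layer_count}")
print(f"min SJ before blending: {mesh.provenance['sj_pre_blend_min']:.3f}")
print(f"min SJ after blending:  {sj.min():.3f}")
print(f"mean in-plane edge: {hs.inplane_edge_lengths(mesh).mean():.2f} mm")
print(f"bone fusion: {mesh.provenance['blend']['fusion']}, fallbacks: {mesh.provenance['fallbacks']}")
```

prints

```
elements: 5456  layers: 4
min SJ before blending: 0.967
min SJ after blending:  0.274
mean in-plane edge: 1.01 mm
bone fusion: full, fallbacks: []
```

The condyle phantom (2 mm cartilage on an R = 30 mm condyle) meshes
into 5456 hexes in four depth layers at ~1 mm in-plane edges. Before
blending every element exceeds the SJ 0.5 gate; blending deliberately
trades some edge-element quality (min SJ drops to 0.27, still positive)
for a smooth 45° cartilage-bone transition, with every bone-side edge
node fused to the bone mesh and no fallbacks needed.

The same steps are available from the shell:

```sh
hexcart phantom --style femoral --out ph/
hexcart mesh --cartilage ph/femoral_cartilage.stl --site femoral \
             --bone ph/femur.stl --out condyle.vtu
hexcart pipeline --recipe recipe.json --out bundle/   # full chain
```

## Layout

| module | role |
| --- | --- |
| `hexcart.phantoms` | synthetic label volumes, ground-truth surfaces, template atlas |
| `hexcart.reconstruct` | closing, marching cubes, component filter, decimation, smoothing, repair |
| `hexcart.bone_remesh` | isotropic Voronoi-clustering bone remeshing |
| `hexcart.hexsweep` | sweep grids, hex sheets, degenerate taxonomy/repair, optimization, subdivision, fallback cascade |
| `hexcart.blend` | cartilage-to-bone edge blending |
| `hexcart.attach` | similarity ICP and attachment-site mapping |
| `hexcart.metrics` | scaled Jacobian, feature angles, surface deviation/coverage, Dice, min-max RMS |
| `hexcart.fileio`, `hexcart.config`, `hexcart.pipeline`, `hexcart.cli` | formats (STL/PLY/VTK/VTU/NIfTI/NRRD/INP), validated config, orchestration with worker pools, CLI |

See `docs/methods.md` for the modelling assumptions, parameter
defaults, numerical choices and known limitations.
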