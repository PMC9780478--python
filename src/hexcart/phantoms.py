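"""Synthetic phantoms: label volumes plus matched ground-truth surfaces.

Stand-ins for restricted knee MRI segmentations. Every phantom is defined
by exact implicit occupancy functions (laminar cartilage shells of known
thickness draped over flat or cylindrical bone, with optional cylindrical
through-holes). The label volume samples the occupancy at cell centres;
ground-truth surfaces are extracted from the same occupancy by marching
cubes at the voxel spacing, so they are faithful to the analytic geometry
to sub-voxel error while remaining closed 2-manifolds for arbitrary hole
layouts. All phantoms are deterministic given their parameters.

Holes are right cylinders through the full cartilage depth, specified as
``(cx, cy, r)`` in millimetres in the *developed* (unrolled) tangent
coordinates of the cartilage patch, emulating the focal full-thickness
cartilage loss seen in degraded joints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from .geometry import MeshProximity, signed_volume
from .volume import DEFAULT_TISSUE_CODES, LabelVolume

_PAD = 2  # voxels of empty padding around every label volume


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Phantom:
    """Label volume + per-tissue ground-truth surfaces + analytic truth."""

    label_volume: LabelVolume
    surfaces: dict[str, trimesh.Trimesh]
    ground_truth: dict = field(default_factory=dict)


@dataclass
class TemplateAtlas:
    """Template femur surface with named attachment sites and axis points."""

    femur_surface: trimesh.Trimesh
    sites: list[tuple[str, str, np.ndarray]]  # (name, tissue, xyz mm)
    joint_axis_points: list[np.ndarray]

    def site_array(self) -> np.ndarray:
        return np.array([xyz for _, _, xyz in self.sites])


# ---------------------------------------------------------------------------
# implicit sampling helpers
# ---------------------------------------------------------------------------

def _sample_grid(bounds, spacing):
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    spacing = np.broadcast_to(np.asarray(spacing, float), 3).copy()
    lo = lo - _PAD * spacing
    n = np.ceil((hi - lo) / spacing).astype(int) + 1 + _PAD
    origin = lo + 0.5 * spacing  # cell-centred samples
    return origin, spacing, n


def _occupancy(occ_fn, origin, spacing, n):
    ii, jj, kk = np.meshgrid(*(np.arange(m) for m in n), indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * spacing + origin
    return occ_fn(pts).reshape(tuple(n))


def extract_isosurface(occ_fn, bounds, spacing, antialias_sigma=0.8) -> trimesh.Trimesh:
    """Closed, outward-oriented marching-cubes surface of an occupancy field.

    A symmetric Gaussian pre-filter (``antialias_sigma`` voxels) removes
    the lattice faceting marching cubes produces on binary fields without
    measurably moving the 0.5-level surface.
    """
    origin, spacing, n = _sample_grid(bounds, spacing)
    occ = _occupancy(occ_fn, origin, spacing, n).astype(np.float32)
    occ = np.pad(occ, 2)  # guarantee closure at the grid boundary
    if antialias_sigma > 0:
        from scipy.ndimage import gaussian_filter

        occ = gaussian_filter(occ, antialias_sigma)
    verts, faces, _, _ = marching_cubes(occ, level=0.5, spacing=tuple(spacing))
    verts = verts + (origin - 2 * spacing)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if signed_volume(mesh.vertices.view(np.ndarray), mesh.faces.view(np.ndarray)) < 0:
        mesh.invert()
    return mesh


def _label_from_occupancies(tissue_occs: dict[str, callable], bounds, spacing):
    origin, spacing, n = _sample_grid(bounds, spacing)
    codes = np.zeros(tuple(n), dtype=np.int16)
    tissue_map = {}
    for name, occ_fn in tissue_occs.items():
        code = DEFAULT_TISSUE_CODES.get(name, max(list(tissue_map) or [0]) + 1)
        codes[_occupancy(occ_fn, origin, spacing, n)] = code
        tissue_map[code] = name
    return LabelVolume(codes, spacing, origin, tissue_map)


def _subtract_holes(inside, dev_u, dev_v, hole_specs):
    for cx, cy, r in hole_specs:
        inside &= (dev_u - cx) ** 2 + (dev_v - cy) ** 2 >= r**2
    return inside


# ---------------------------------------------------------------------------
# slab phantom
# ---------------------------------------------------------------------------

def make_slab_phantom(
    length_mm: float = 20.0,
    width_mm: float = 10.0,
    thickness_mm: float = 3.0,
    curvature_radius_mm: float | None = None,
    hole_specs=(),
    voxel_spacing_mm: float = 0.5,
    bone_thickness_mm: float = 4.0,
) -> Phantom:
    """Cartilage slab (flat, or draped on a cylinder) over a bone layer.

    The slab occupies ``|u| <= length/2, |y| <= width/2`` in developed
    coordinates, with the bone-side surface at offset 0 and joint-side at
    ``thickness``. ``curvature_radius_mm`` bends the slab about the width
    (y) axis, apex at the origin, convex toward +z.
    """
    L, W, T, R = length_mm, width_mm, thickness_mm, curvature_radius_mm
    s = voxel_spacing_mm
    if T < 2 * s:
        raise ValueError(
            f"thickness {T} mm below resolvable limit (2 x spacing = {2 * s} mm)"
        )
    B = bone_thickness_mm
    for cx, cy, r in hole_specs:
        if abs(cx) - r > L / 2 or abs(cy) - r > W / 2:
            raise ValueError(f"hole ({cx},{cy},{r}) lies outside the slab footprint")

    if R is None:
        def developed(pts):
            return pts[:, 0], pts[:, 1], pts[:, 2]  # u, v, height above bone
    else:
        if R <= L:
            raise ValueError("curvature radius must exceed the slab length")

        def developed(pts):
            x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
            rad = np.sqrt(x**2 + (z + R) ** 2)  # axis at (0, y, -R)
            u = R * np.arctan2(x, z + R)
            return u, y, rad - R

    def cart_occ(pts):
        u, v, h = developed(pts)
        inside = (np.abs(u) <= L / 2) & (np.abs(v) <= W / 2) & (h >= 0) & (h <= T)
        return _subtract_holes(inside, u, v, hole_specs)

    def bone_occ(pts):
        u, v, h = developed(pts)
        return (np.abs(u) <= L / 2) & (np.abs(v) <= W / 2) & (h >= -B) & (h < 0)

    zmax = T if R is None else T + 1.0
    zmin = -B if R is None else -B - (R - np.sqrt(max(R**2 - (L / 2) ** 2, 0.0)))
    bounds = ([-L / 2, -W / 2, zmin], [L / 2, W / 2, zmax])
    label = _label_from_occupancies(
        {"bone": bone_occ, "cartilage": cart_occ}, bounds, s
    )
    surfaces = {
        "bone": extract_isosurface(bone_occ, bounds, s),
        "cartilage": extract_isosurface(cart_occ, bounds, s),
    }
    gt = {
        "style": "slab",
        "thickness_mm": T,
        "curvature_radius_mm": R,
        "length_mm": L,
        "width_mm": W,
        "holes": [tuple(h) for h in hole_specs],
        "voxel_spacing_mm": s,
    }
    return Phantom(label, surfaces, gt)


# ---------------------------------------------------------------------------
# joint phantoms
# ---------------------------------------------------------------------------

def _ellipse_mask(x, y, center, semi):
    return ((x - center[0]) / semi[0]) ** 2 + ((y - center[1]) / semi[1]) ** 2 <= 1.0


def make_joint_phantom(
    style: str,
    thickness_mm: float = 2.0,
    hole_specs=(),
    voxel_spacing_mm: float = 0.5,
    **size,
) -> Phantom:
    """Bone + conforming cartilage shell mimicking one knee compartment.

    styles:
      * ``femoral``  — condylar cylinder (radius ``radius_mm``, axis along y)
        with a cartilage shell wrapped over ``wrap_deg`` degrees;
      * ``tibial``   — flat plateau with two elliptical compartments
        (independent medial/lateral labels);
      * ``patellar`` — single flat elliptical patch on a bone slab.
    """
    T = thickness_mm
    s = voxel_spacing_mm
    if T < 2 * s:
        raise ValueError(
            f"thickness {T} mm below resolvable limit (2 x spacing = {2 * s} mm)"
        )

    if style == "femoral":
        R = float(size.get("radius_mm", 30.0))
        W = float(size.get("width_mm", 25.0))
        wrap = np.deg2rad(float(size.get("wrap_deg", 120.0)))
        Wb = W + 4.0

        def developed(pts):
            x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
            return R * np.arctan2(x, z), y, np.sqrt(x**2 + z**2) - R

        def cart_occ(pts):
            u, v, h = developed(pts)
            inside = (
                (np.abs(u) <= R * wrap / 2)
                & (np.abs(v) <= W / 2)
                & (h >= 0)
                & (h <= T)
                & (pts[:, 2] > 0)
            )
            return _subtract_holes(inside, u, v, hole_specs)

        def bone_occ(pts):
            x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
            return (x**2 + z**2 <= R**2) & (np.abs(y) <= Wb / 2)

        lim = R + T + 1
        bounds = ([-lim, -Wb / 2, -lim], [lim, Wb / 2, lim])
        tissues = {"femur": bone_occ, "femoral_cartilage": cart_occ}
        surface_names = ["femur", "femoral_cartilage"]
        gt_extra = {"radius_mm": R, "width_mm": W, "wrap_deg": np.rad2deg(wrap)}

    elif style == "tibial":
        L = float(size.get("length_mm", 50.0))
        W = float(size.get("width_mm", 28.0))
        B = float(size.get("bone_thickness_mm", 4.0))
        margin = 2.0
        centers = [(-L / 4, 0.0), (L / 4, 0.0)]
        semi = (L / 4 - margin, W / 2 - margin)

        def compartment_occ(center):
            def occ(pts):
                x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
                inside = _ellipse_mask(x, y, center, semi) & (z >= 0) & (z <= T)
                return _subtract_holes(inside, x, y, hole_specs)

            return occ

        def bone_occ(pts):
            x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
            return (np.abs(x) <= L / 2) & (np.abs(y) <= W / 2) & (z >= -B) & (z < 0)

        bounds = ([-L / 2, -W / 2, -B], [L / 2, W / 2, T])
        tissues = {
            "tibia": bone_occ,
            "tibial_cartilage_medial": compartment_occ(centers[0]),
            "tibial_cartilage_lateral": compartment_occ(centers[1]),
        }
        surface_names = list(tissues)
        # flag holes that cross the scaled-bounding-box edge of a
        # compartment footprint: such geometry exercises the fallback grid
        crosses = False
        scale = 0.9
        for cx0, cy0 in centers:
            half = np.array([semi[0], semi[1]]) * scale
            for cx, cy, r in hole_specs:
                d = np.abs(np.array([cx - cx0, cy - cy0]))
                outside = np.any(d - r > half)
                fully_inside = np.all(d + r < half)
                if not outside and not fully_inside:
                    crosses = True
        gt_extra = {
            "length_mm": L,
            "width_mm": W,
            "compartment_centers": centers,
            "compartment_semiaxes": semi,
            "exercises_fallback_grid": crosses,
        }

    elif style == "patellar":
        L = float(size.get("length_mm", 26.0))
        W = float(size.get("width_mm", 20.0))
        B = float(size.get("bone_thickness_mm", 4.0))
        margin = 2.0
        semi = (L / 2 - margin, W / 2 - margin)

        def cart_occ(pts):
            x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
            inside = _ellipse_mask(x, y, (0.0, 0.0), semi) & (z >= 0) & (z <= T)
            return _subtract_holes(inside, x, y, hole_specs)

        def bone_occ(pts):
            x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
            return (np.abs(x) <= L / 2) & (np.abs(y) <= W / 2) & (z >= -B) & (z < 0)

        bounds = ([-L / 2, -W / 2, -B], [L / 2, W / 2, T])
        tissues = {"patella": bone_occ, "patellar_cartilage": cart_occ}
        surface_names = list(tissues)
        gt_extra = {"length_mm": L, "width_mm": W}

    else:
        raise ValueError(f"unknown joint phantom style: {style!r}")

    label = _label_from_occupancies(tissues, bounds, s)
    surfaces = {name: extract_isosurface(tissues[name], bounds, s) for name in surface_names}
    gt = {
        "style": style,
        "thickness_mm": T,
        "holes": [tuple(h) for h in hole_specs],
        "voxel_spacing_mm": s,
        **gt_extra,
    }
    return Phantom(label, surfaces, gt)


# ---------------------------------------------------------------------------
# template atlas
# ---------------------------------------------------------------------------

def make_template_atlas(n_sites: int = 160, surface_spacing_mm: float = 1.0) -> TemplateAtlas:
    """Deterministic synthetic femur template with named attachment sites.

    Sites are spread over the condylar surface at golden-ratio parametric
    locations and projected exactly onto the template surface; two axis
    points mark the (medial-lateral) cylinder axis, standing in for an
    epicondylar joint axis.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    R, Wb = 30.0, 29.0

    def bone_occ(pts):
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        return (x**2 + z**2 <= R**2) & (np.abs(y) <= Wb / 2)

    lim = R + 1
    femur = extract_isosurface(
        bone_occ, ([-lim, -Wb / 2, -lim], [lim, Wb / 2, lim]), surface_spacing_mm
    )

    phi = (1 + np.sqrt(5)) / 2
    k = np.arange(n_sites)
    theta = 2 * np.pi * ((k * phi) % 1.0) - np.pi  # angle about the axis
    yy = (((k + 0.5) / n_sites) - 0.5) * (Wb - 2.0)
    param = np.column_stack([R * np.sin(theta), yy, R * np.cos(theta)])
    prox = MeshProximity(femur.vertices.view(np.ndarray), femur.faces.view(np.ndarray))
    snapped, _, _ = prox.query(param)
    sites = [
        (f"site_{i:03d}", "femur", snapped[i].copy()) for i in range(n_sites)
    ]
    axis_points = [np.array([0.0, -Wb / 2, 0.0]), np.array([0.0, Wb / 2, 0.0])]
    return TemplateAtlas(femur, sites, axis_points)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def voxelize_surface(surface: trimesh.Trimesh, spacing_mm: float, code: int = 1,
                     tissue: str = "tissue") -> LabelVolume:
    """Voxelize a closed surface into an interior-filled label volume."""
    if not surface.is_watertight:
        raise ValueError("voxelize_surface requires a closed (watertight) surface")
    h = float(spacing_mm)
    lo = surface.bounds[0] - _PAD * h
    hi = surface.bounds[1] + _PAD * h
    n = np.ceil((hi - lo) / h).astype(int)
    origin = lo + 0.5 * h  # cell-centred: no centre sits on an axis-aligned face

    verts = surface.vertices.view(np.ndarray)
    faces = surface.faces.view(np.ndarray)
    prox = MeshProximity(verts, faces)
    from .geometry import face_normals

    fn = face_normals(verts, faces)
    ii, jj, kk = np.meshgrid(*(np.arange(m) for m in n), indexing="ij")
    centers = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * h + origin
    inside = np.zeros(len(centers), dtype=bool)
    for start in range(0, len(centers), 65536):
        sl = slice(start, start + 65536)
        cp, _, tri = prox.query(centers[sl])
        inside[sl] = np.einsum("ij,ij->i", centers[sl] - cp, fn[tri]) < 0
    codes = np.zeros(tuple(n), dtype=np.int16)
    codes[inside.reshape(tuple(n))] = code
    return LabelVolume(codes, [h] * 3, origin, {code: tissue})
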