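"""Swept-extrusion hexahedral cartilage meshing.

A laminar cartilage shell is meshed by raytracing two matching
rectangular grids of surface points — one on the bone-side surface, one
on the joint-side surface — and connecting them through the thickness
into a single layer of hexahedra. Boundary cells with only three valid
grid corners enter as six-node degenerates, are classified into the
peak / mirror / stair / step / corner taxonomy and repaired, the sheet
is optimized to a non-negative scaled Jacobian, subdivided 2x2 in-plane,
optimized again to SJ > 0.5, optionally blended into the bone, and
finally subdivided into depth layers.

Ray layouts:

* femoral / patellar sites sweep origins along a fitted cylinder axis
  (medial-lateral) and fan radial rays; a near-flat patch degenerates
  gracefully to quasi-parallel rays through a capped fit radius.
* tibial sites project along the plateau normal, discard back faces,
  and trace either a radial-sector grid seeded from a scaled bounding
  box of the footprint or — as a fallback — a rectilinear grid on the
  unscaled box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateClassificationError,
    MeshingError,
    QualityError,
    StrategyFailure,
)
from .geometry import MeshProximity, face_normals, ray_mesh_intersections
from .metrics import scaled_jacobian
from .params import MeshParams, SweepParams

# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SweepGrid:
    """Paired rectangular grids of bone-side / joint-side ray hits."""

    origins: np.ndarray     # (m,n,3)
    directions: np.ndarray  # (m,n,3) unit rays
    bone_hits: np.ndarray   # (m,n,3)
    joint_hits: np.ndarray  # (m,n,3)
    valid: np.ndarray       # (m,n) bool
    site: str
    strategy: str
    pitch: float

    @property
    def shape(self):
        return self.valid.shape


@dataclass
class WedgeInfo:
    """Bookkeeping for one six-node (wedge) element."""

    elem: int
    cell: tuple          # (i,j) grid cell
    miss_local: int      # missing corner position in the CCW cell loop
    target_local: int    # corner the missing one collapsed onto
    miss_grid: tuple     # (gi,gj) grid index of the missing corner


@dataclass
class DegenerateRecord:
    element_ids: list
    klass: str  # peak | mirror | stair | step | corner
    shared_topological_indices: tuple = ()


@dataclass
class HexSheet:
    """Single-layer hex sheet with bone/joint node pairing."""

    nodes: np.ndarray          # (N,3)
    hexes: np.ndarray          # (E,8): bone quad CCW then joint quad
    partner: np.ndarray        # (N,) node id of the through-thickness mate
    is_bone: np.ndarray        # (N,) bool
    wedges: list = field(default_factory=list)
    grid: SweepGrid | None = None

    # -- derived surfaces --------------------------------------------------
    def bone_quads(self) -> np.ndarray:
        return self.hexes[:, :4]

    def joint_quads(self) -> np.ndarray:
        return self.hexes[:, 4:]

    def copy(self) -> "HexSheet":
        return HexSheet(
            self.nodes.copy(), self.hexes.copy(), self.partner.copy(),
            self.is_bone.copy(), list(self.wedges), self.grid,
        )

    def element_corners(self) -> np.ndarray:
        return self.nodes[self.hexes]

    def scaled_jacobians(self) -> np.ndarray:
        return scaled_jacobian(self.element_corners())

    def boundary_nodes(self) -> np.ndarray:
        """Bone-side node ids on the sheet boundary (cartilage edge)."""
        edges = quad_edges(self.bone_quads())
        key, counts = np.unique(np.sort(edges.reshape(-1, 2), axis=1), axis=0, return_counts=True)
        rim = key[counts == 1]
        return np.unique(rim)


@dataclass
class HexMesh:
    """Depth-subdivided hexahedral mesh with meshing provenance."""

    nodes: np.ndarray
    hexes: np.ndarray
    layer_count: int
    layer_of: np.ndarray            # (E,) depth-layer index, 0 = bone side
    provenance: dict = field(default_factory=dict)

    def scaled_jacobians(self) -> np.ndarray:
        return scaled_jacobian(self.nodes[self.hexes])

    def is_conforming(self) -> bool:
        faces = hex_faces(self.hexes).reshape(-1, 4)
        key = np.sort(faces, axis=1)
        _, counts = np.unique(key, axis=0, return_counts=True)
        return bool(counts.max(initial=0) <= 2)

    def boundary_quads(self) -> np.ndarray:
        faces = hex_faces(self.hexes).reshape(-1, 4)
        key = np.sort(faces, axis=1)
        uniq, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return faces[np.isin(inv, np.nonzero(counts == 1)[0])]


# local face table of a hex (bottom, top, 4 sides)
_HEX_FACES = np.array(
    [
        [0, 3, 2, 1],  # bone side (outward = -depth)
        [4, 5, 6, 7],  # joint side
        [0, 1, 5, 4],
        [1, 2, 6, 5],
        [2, 3, 7, 6],
        [3, 0, 4, 7],
    ]
)


def hex_faces(hexes: np.ndarray) -> np.ndarray:
    """(E,6,4) face-node table of each hex."""
    return np.asarray(hexes)[:, _HEX_FACES]


def quad_edges(quads: np.ndarray) -> np.ndarray:
    """(Q,4,2) directed edge list of quads."""
    q = np.asarray(quads)
    return np.stack([q, np.roll(q, -1, axis=1)], axis=-1)


# ---------------------------------------------------------------------------
# ray casting onto the shell
# ---------------------------------------------------------------------------


def _cast_grid(origins, directions, surface):
    """Bone/joint hit pair per ray by entering/exiting classification."""
    V = surface.vertices.view(np.ndarray)
    F = surface.faces.view(np.ndarray)
    fn = face_normals(V, F)
    m, n = origins.shape[:2]
    o = origins.reshape(-1, 3)
    d = directions.reshape(-1, 3)
    ri, t, ti, pts = ray_mesh_intersections(o, d, V, F)

    first_hit = np.full((m * n, 3), np.nan)
    last_hit = np.full((m * n, 3), np.nan)
    have_first = np.zeros(m * n, dtype=bool)
    have_last = np.zeros(m * n, dtype=bool)
    entering = np.einsum("ij,ij->i", fn[ti], d[ri]) < 0.0

    # hits arrive sorted by (ray, t); deduplicate near-equal t per ray
    prev_ray = -1
    prev_t = -np.inf
    for k in range(len(ri)):
        r = ri[k]
        if r == prev_ray and abs(t[k] - prev_t) < 1e-7:
            continue
        prev_ray, prev_t = r, t[k]
        if entering[k] and not have_first[r]:
            first_hit[r] = pts[k]
            have_first[r] = True
        if not entering[k]:
            last_hit[r] = pts[k]
            have_last[r] = True

    valid = have_first & have_last
    depth = np.linalg.norm(last_hit - first_hit, axis=1)
    valid &= depth > 1e-9
    return (
        first_hit.reshape(m, n, 3),
        last_hit.reshape(m, n, 3),
        valid.reshape(m, n),
        depth.reshape(m, n),
    )


def _principal_frame(points):
    c = points.mean(axis=0)
    u, s, vt = np.linalg.svd(points - c, full_matrices=False)
    return c, vt  # rows: descending-variance axes


def _fit_cylinder_axis(surface, max_radius, bone_hint=None):
    """Axis direction/point and radius of the best-fit cylinder.

    Axis direction: null direction of the face-normal covariance
    (cylinder normals live in the plane perpendicular to the axis);
    position/radius: algebraic (Kasa) circle fit of the projected
    vertices. The fit is accepted only when the shell really is a thin
    annulus sector around the axis; otherwise (flat or weakly curved
    patches) the axis is placed ``max_radius`` beneath the patch so the
    fan degrades to quasi-parallel rays.
    """
    V = surface.vertices.view(np.ndarray)
    F = surface.faces.view(np.ndarray)
    fn = face_normals(V, F)
    tri = V[F]
    w = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    cov = (fn * w[:, None]).T @ fn
    evals, evecs = np.linalg.eigh(cov)
    a_dir = evecs[:, 0]  # smallest normal variance

    # in-plane basis
    tmp = np.array([1.0, 0, 0]) if abs(a_dir[0]) < 0.9 else np.array([0, 1.0, 0])
    e1 = np.cross(a_dir, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a_dir, e1)
    u = V @ e1
    v = V @ e2
    A = np.column_stack([2 * u, 2 * v, np.ones(len(u))])
    b = u**2 + v**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cu, cv, dd = sol
    r2 = dd + cu**2 + cv**2
    radius = np.sqrt(max(r2, 0.0))

    fit_ok = np.isfinite(radius) and 0 < radius <= max_radius
    if fit_ok:
        # the shell must be a thin annulus around the fitted axis, or
        # the axis may sit inside the slab and rays would start interior
        r_all = np.hypot(u - cu, v - cv)
        fit_ok = (r_all.max() - r_all.min()) < 0.5 * r_all.mean()
    if not fit_ok:
        c, vt = _principal_frame(V)
        up = vt[2]
        if bone_hint is not None and (c - np.asarray(bone_hint)) @ up < 0:
            up = -up  # axis goes on the bone side of the patch
        center = c - max_radius * up
        radius = max_radius
        cu, cv = center @ e1, center @ e2
    axis_point = cu * e1 + cv * e2
    return a_dir, axis_point, float(radius), (e1, e2)


def _largest_true_component(mask):
    lab, n = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return lab == keep


def make_sweep_grid(
    cartilage_surface,
    site: str,
    target_edge_mm: float = 1.0,
    strategy: str | None = None,
    params: SweepParams | None = None,
    bone_hint=None,
) -> SweepGrid:
    """Build the paired bone-/joint-side ray-hit grids for one tissue."""
    params = params or SweepParams(target_edge_mm=target_edge_mm)
    pitch = 2.0 * target_edge_mm
    V = cartilage_surface.vertices.view(np.ndarray)

    if site in ("femoral", "patellar"):
        strategy = strategy or "cylindrical"
        a_dir, axis_point, radius, (e1, e2) = _fit_cylinder_axis(
            cartilage_surface, params.max_fit_radius_mm, bone_hint
        )
        rel = V - axis_point
        s_axis = rel @ a_dir
        radial = rel - np.outer(s_axis, a_dir)
        r_surf = np.linalg.norm(radial, axis=1)
        # orient the fan toward the surface: reference = mean radial dir
        ref = radial.mean(axis=0)
        ref /= np.linalg.norm(ref)
        ref2 = np.cross(a_dir, ref)
        theta = np.arctan2(radial @ ref2, radial @ ref)
        if bone_hint is not None:
            # bone side must face the bone: flip the axis to the far side
            # if the hint is radially outside the shell
            pass
        m = max(2, int(np.ceil((s_axis.max() - s_axis.min()) / pitch)) + 1)
        r_mean = float(r_surf.mean())
        arc = (theta.max() - theta.min()) * r_mean
        n = max(2, int(np.ceil(arc / pitch)) + 1)
        s_vals = np.linspace(s_axis.min(), s_axis.max(), m)
        t_vals = np.linspace(theta.min(), theta.max(), n)
        ss, tt = np.meshgrid(s_vals, t_vals, indexing="ij")
        origins = axis_point + ss[..., None] * a_dir
        directions = (
            np.cos(tt)[..., None] * ref + np.sin(tt)[..., None] * ref2
        )
    elif site == "tibial":
        strategy = strategy or "sectors"
        c, vt = _principal_frame(V)
        w = vt[2]  # projection axis (plateau normal)
        if bone_hint is not None and (c - np.asarray(bone_hint)) @ w < 0:
            w = -w
        e1, e2 = vt[0], vt[1]
        VF = cartilage_surface.faces.view(np.ndarray)
        fn = face_normals(V, VF)
        front = fn @ w > 0.0  # discard back faces under the projection
        fverts = np.unique(VF[front])
        u = (V[fverts] - c) @ e1
        v = (V[fverts] - c) @ e2
        height = (V - c) @ w
        if strategy == "sectors":
            # radial-sector interior grid seeded from the *scaled*
            # bounding box: the unit square is mapped onto the inscribed
            # ellipse (square-to-disk elliptical map), so grid lines fan
            # radially toward the rim without a polar seam or pole
            scale = params.tibial_bbox_scale
            half_u = scale * max(abs(u.min()), abs(u.max()))
            half_v = scale * max(abs(v.min()), abs(v.max()))
            m = max(3, int(np.ceil(2 * half_u / pitch)) + 1)
            n = max(3, int(np.ceil(2 * half_v / pitch)) + 1)
            xi, eta = np.meshgrid(
                np.linspace(-1, 1, m), np.linspace(-1, 1, n), indexing="ij"
            )
            uu = half_u * xi * np.sqrt(1 - eta**2 / 2)
            vv = half_v * eta * np.sqrt(1 - xi**2 / 2)
        elif strategy == "rectilinear":
            uu_1 = np.arange(u.min(), u.max() + pitch * 0.5, pitch)
            vv_1 = np.arange(v.min(), v.max() + pitch * 0.5, pitch)
            if len(uu_1) < 2 or len(vv_1) < 2:
                raise StrategyFailure("footprint smaller than one grid pitch")
            uu, vv = np.meshgrid(uu_1, vv_1, indexing="ij")
        else:
            raise ValueError(f"unknown tibial strategy {strategy!r}")
        top = height.max() + 1.0
        origins = c + uu[..., None] * e1 + vv[..., None] * e2 + top * w
        directions = np.broadcast_to(-w, origins.shape).copy()
    else:
        raise ValueError(f"unknown site {site!r}")

    first, last, valid, depth = _cast_grid(origins, directions, cartilage_surface)
    if site == "tibial":
        joint_hits, bone_hits = first, last  # rays travel joint -> bone
    else:
        bone_hits, joint_hits = first, last  # radial rays exit joint side

    # depth sanity filter drops rays clipping side walls
    med = np.median(depth[valid]) if valid.any() else 0.0
    if med > 0:
        lo, hi = params.depth_filter
        valid &= np.where(np.isnan(depth), False, (depth > lo * med) & (depth < hi * med))
    n_hit_any = int((~np.isnan(depth)).sum())
    if n_hit_any == 0 or valid.sum() < params.min_valid_fraction * n_hit_any:
        raise StrategyFailure(
            f"{site}/{strategy}: only {int(valid.sum())} of {n_hit_any} "
            "interior rays hit both surfaces"
        )
    valid = _largest_true_component(valid)
    return SweepGrid(
        origins, directions, bone_hits, joint_hits, valid, site, strategy, pitch
    )


# ---------------------------------------------------------------------------
# sheet construction
# ---------------------------------------------------------------------------


def build_hex_sheet(grid: SweepGrid) -> HexSheet:
    """Connect the matched grids into a single-layer hex sheet.

    Cells with 4 valid corners yield full hexes; cells with exactly 3
    yield six-node degenerates, the missing corner collapsed onto its
    CCW-next valid neighbour (recorded for classification).
    """
    m, n = grid.shape
    valid = grid.valid
    node_id = np.full((m, n), -1, dtype=np.int64)
    gi, gj = np.nonzero(valid)
    node_id[gi, gj] = np.arange(len(gi))
    K = len(gi)
    if K < 3:
        raise MeshingError("sweep grid has fewer than 3 valid nodes")

    bone_nodes = grid.bone_hits[gi, gj]
    joint_nodes = grid.joint_hits[gi, gj]
    nodes = np.concatenate([bone_nodes, joint_nodes])
    partner = np.concatenate([np.arange(K) + K, np.arange(K)])
    is_bone = np.zeros(2 * K, dtype=bool)
    is_bone[:K] = True

    # decide cell corner winding once so elements come out positive
    def corners(i, j, flip):
        loop = [(i, j), (i + 1, j), (i + 1, j + 1), (i, j + 1)]
        return loop[::-1] if flip else loop

    flip = False
    probe = None
    for i in range(m - 1):
        for j in range(n - 1):
            cs = corners(i, j, False)
            if all(valid[c] for c in cs):
                probe = cs
                break
        if probe:
            break
    if probe:
        b = [node_id[c] for c in probe]
        elem = np.array(b + [partner[x] for x in b])
        if scaled_jacobian(nodes[elem]) < 0:
            flip = True

    hexes = []
    wedges = []
    for i in range(m - 1):
        for j in range(n - 1):
            cs = corners(i, j, flip)
            ok = [valid[c] for c in cs]
            nv = sum(ok)
            if nv < 3:
                continue
            if nv == 4:
                b = [int(node_id[c]) for c in cs]
                hexes.append(b + [int(partner[x]) for x in b])
            else:
                q = ok.index(False)
                tgt = (q + 1) % 4
                b = [int(node_id[cs[k]]) if ok[k] else -1 for k in range(4)]
                b[q] = b[tgt]
                elem_id = len(hexes)
                hexes.append(b + [int(partner[x]) for x in b])
                wedges.append(
                    WedgeInfo(elem_id, (i, j), q, tgt, cs[q])
                )
    if not hexes:
        raise MeshingError("no cells with at least 3 valid corners")
    hexes = np.asarray(hexes, dtype=np.int64)

    # drop unused nodes
    used = np.unique(hexes)
    remap = np.full(len(nodes), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sheet = HexSheet(
        nodes[used],
        remap[hexes],
        remap[partner[used]],
        is_bone[used],
        wedges,
        grid,
    )
    if (sheet.partner < 0).any():
        raise MeshingError("internal pairing error: partner of used node dropped")
    return sheet


# ---------------------------------------------------------------------------
# degenerate taxonomy
# ---------------------------------------------------------------------------

# Cell-corner loop positions adjacent to corner q (shared cell edges)
def _collapse_targets(sheet, w: WedgeInfo):
    """Element-local index pair carrying the repeated (degenerate) node."""
    return tuple(sorted((w.miss_local, w.target_local)))


def classify_degenerates(sheet: HexSheet) -> list[DegenerateRecord]:
    """Group six-node elements into peak/mirror/stair/step/corner records.

    * isolated wedge with >= 2 full-hex cell neighbours -> ``corner``
      (interior concave corner of the valid mask);
    * isolated wedge otherwise -> ``peak`` (protruding tip);
    * two edge-adjacent wedges whose missing corners collapse onto one
      common valid node of the shared cell edge (same element-local
      degenerate indices) -> ``step``;
    * two edge-adjacent wedges otherwise -> ``mirror``;
    * three wedges in an adjacency chain -> ``stair``;
    * anything larger -> :class:`DegenerateClassificationError`.
    """
    if not sheet.wedges:
        return []
    if sheet.grid is None:
        raise DegenerateClassificationError(
            "sheet lost its grid provenance", [w.elem for w in sheet.wedges]
        )
    valid = sheet.grid.valid
    m, n = valid.shape
    by_cell = {w.cell: w for w in sheet.wedges}

    # full cells (4 valid corners)
    def is_full(i, j):
        if not (0 <= i < m - 1 and 0 <= j < n - 1):
            return False
        if (i, j) in by_cell:
            return False
        return all(
            valid[c] for c in [(i, j), (i + 1, j), (i + 1, j + 1), (i, j + 1)]
        )

    # wedge adjacency graph (4-neighbourhood of cells)
    cells = list(by_cell)
    seen = set()
    groups = []
    for c in cells:
        if c in seen:
            continue
        stack, comp = [c], []
        seen.add(c)
        while stack:
            cur = stack.pop()
            comp.append(cur)
            i, j = cur
            for nb in ((i + 1, j), (i - 1, j), (i, j + 1), (i, j - 1)):
                if nb in by_cell and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        groups.append(comp)

    records = []
    for comp in groups:
        ws = [by_cell[c] for c in comp]
        ids = [w.elem for w in ws]
        if len(comp) == 1:
            (i, j) = comp[0]
            n_full = sum(
                is_full(*nb) for nb in ((i + 1, j), (i - 1, j), (i, j + 1), (i, j - 1))
            )
            klass = "corner" if n_full >= 2 else "peak"
            records.append(
                DegenerateRecord(ids, klass, _collapse_targets(sheet, ws[0]))
            )
        elif len(comp) == 2:
            w1, w2 = ws
            # step: the two missing corners are distinct and both
            # grid-adjacent to one common *valid* node shared by the two
            # cells (the staircase apex) — both collapses then target the
            # same node, i.e. the degenerate nodes sit at the same
            # element-local (topological) indices. Two cells missing the
            # *same* shared node, or any other arrangement, mirror the
            # notch instead.
            def cell_nodes(cell):
                i, j = cell
                return {(i, j), (i + 1, j), (i + 1, j + 1), (i, j + 1)}

            def grid_adjacent(a, b):
                return abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1

            klass = "mirror"
            shared_idx = ()
            if w1.miss_grid != w2.miss_grid:
                shared_nodes = cell_nodes(w1.cell) & cell_nodes(w2.cell)
                for apex in shared_nodes:
                    if (
                        valid[apex]
                        and grid_adjacent(apex, w1.miss_grid)
                        and grid_adjacent(apex, w2.miss_grid)
                    ):
                        klass = "step"
                        shared_idx = _collapse_targets(sheet, w1)
                        break
            records.append(DegenerateRecord(ids, klass, shared_idx))
        elif len(comp) == 3:
            records.append(DegenerateRecord(ids, "stair"))
        else:
            raise DegenerateClassificationError(
                f"unclassifiable degenerate cluster of {len(comp)} wedges",
                ids,
            )
    return records


def repair_degenerates(
    sheet: HexSheet, records: list[DegenerateRecord], surface=None
) -> HexSheet:
    """Return a sheet in which every element has 8 distinct nodes.

    Class rules: ``corner`` wedges get their missing grid corner
    reconstructed by linear extrapolation of neighbouring ray hits (node
    creation, re-projected onto the cartilage surface when given); all
    other classes remove the offending elements (peak: 1, step/mirror:
    2, stair: 3), trimming the ragged boundary.
    """
    if not records:
        return sheet.copy()
    grid = sheet.grid
    valid = grid.valid
    m, n = valid.shape
    nodes = [sheet.nodes.copy()]
    partner = list(sheet.partner)
    is_bone = list(sheet.is_bone)
    hexes = sheet.hexes.copy()
    delete = set()
    by_elem = {w.elem: w for w in sheet.wedges}
    prox = None
    if surface is not None:
        prox = MeshProximity(
            surface.vertices.view(np.ndarray), surface.faces.view(np.ndarray)
        )

    def extrapolate(gi, gj, hits):
        cands = []
        for d in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            p1 = (gi + d[0], gj + d[1])
            p2 = (gi + 2 * d[0], gj + 2 * d[1])
            if (
                0 <= p1[0] < m and 0 <= p1[1] < n and valid[p1]
                and 0 <= p2[0] < m and 0 <= p2[1] < n and valid[p2]
            ):
                cands.append(2 * hits[p1] - hits[p2])
        if not cands:
            return None
        return np.mean(cands, axis=0)

    next_id = len(sheet.nodes)
    extra_nodes = []
    for rec in records:
        if rec.klass == "corner":
            w = by_elem[rec.element_ids[0]]
            gi, gj = w.miss_grid
            bpos = extrapolate(gi, gj, grid.bone_hits)
            jpos = extrapolate(gi, gj, grid.joint_hits)
            if bpos is None or jpos is None:
                delete.update(rec.element_ids)  # fall back to trimming
                continue
            if prox is not None:
                snapped, _, _ = prox.query(np.vstack([bpos, jpos]))
                bpos, jpos = snapped
            b_id, j_id = next_id, next_id + 1
            next_id += 2
            extra_nodes.extend([bpos, jpos])
            partner.extend([j_id, b_id])
            is_bone.extend([True, False])
            e = hexes[w.elem]
            e[w.miss_local] = b_id
            e[4 + w.miss_local] = j_id
        else:
            delete.update(rec.element_ids)

    if extra_nodes:
        nodes.append(np.asarray(extra_nodes))
    all_nodes = np.concatenate(nodes)
    keep = np.array([i for i in range(len(hexes)) if i not in delete], dtype=int)
    hexes = hexes[keep]
    if len(hexes) == 0:
        raise MeshingError("degenerate repair removed every element")

    used = np.unique(hexes)
    remap = np.full(len(all_nodes), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    partner = np.asarray(partner)
    out = HexSheet(
        all_nodes[used],
        remap[hexes],
        remap[partner[used]],
        np.asarray(is_bone)[used],
        [],
        grid,
    )
    if (out.partner < 0).any():
        raise MeshingError("repair broke bone/joint pairing")
    # verify: all elements now have 8 distinct nodes
    for e in out.hexes:
        if len(set(e.tolist())) != 8:
            raise MeshingError("degenerate repair left a collapsed element")
    return out


def _rebuild_sheet(sheet: HexSheet, keep: np.ndarray) -> HexSheet:
    """Sheet restricted to element subset ``keep`` (unused nodes dropped)."""
    hexes = sheet.hexes[keep]
    used = np.unique(hexes)
    remap = np.full(len(sheet.nodes), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    out = HexSheet(
        sheet.nodes[used],
        remap[hexes],
        remap[sheet.partner[used]],
        sheet.is_bone[used],
        [],
        sheet.grid,
    )
    if (out.partner < 0).any():
        raise MeshingError("element trimming broke bone/joint pairing")
    return out


def trim_boundary_slivers(sheet: HexSheet, sj_floor: float = 0.15, rounds: int = 5) -> HexSheet:
    """Drop intrinsically hopeless boundary elements.

    Ragged sweep boundaries can leave sliver cells whose in-plane shape
    no amount of node movement can fix; elements touching the boundary
    with SJ below ``sj_floor`` are deleted (repeatedly, since trimming
    exposes new boundary), then the largest element-connected component
    is kept.
    """
    out = sheet
    for _ in range(rounds):
        sj = out.scaled_jacobians()
        rim = set(int(v) for v in out.boundary_nodes())
        touches = np.array(
            [bool(set(map(int, e[:4])) & rim) for e in out.hexes]
        )
        drop = (sj < sj_floor) & touches

        # pinch vertices (rim node on >2 rim edges) make the boundary
        # non-manifold: drop the worst adjacent element to open them up
        edges = quad_edges(out.bone_quads()).reshape(-1, 2)
        key, counts = np.unique(np.sort(edges, axis=1), axis=0, return_counts=True)
        rim_edges = key[counts == 1]
        ids, deg = np.unique(rim_edges, return_counts=True)
        for v in ids[deg > 2]:
            adj = [
                k for k, e in enumerate(out.hexes) if int(v) in set(map(int, e[:4]))
            ]
            if adj:
                drop[min(adj, key=lambda k: sj[k])] = True

        if not drop.any():
            break
        keep = np.nonzero(~drop)[0]
        if len(keep) == 0:
            raise MeshingError("sliver trimming removed every element")
        out = _rebuild_sheet(out, keep)

    # keep the largest component (edge-sharing adjacency of bone quads)
    edges = quad_edges(out.bone_quads())
    key = np.sort(edges.reshape(-1, 2), axis=1)
    owner = np.repeat(np.arange(len(out.hexes)), 4)
    order = np.lexsort((key[:, 1], key[:, 0]))
    key, owner = key[order], owner[order]
    same = (np.diff(key, axis=0) == 0).all(axis=1)
    parent = np.arange(len(out.hexes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k in np.nonzero(same)[0]:
        a, b = find(owner[k]), find(owner[k + 1])
        if a != b:
            parent[a] = b
    roots = np.array([find(i) for i in range(len(out.hexes))])
    vals, counts = np.unique(roots, return_counts=True)
    keep = np.nonzero(roots == vals[np.argmax(counts)])[0]
    if len(keep) < len(out.hexes):
        out = _rebuild_sheet(out, keep)
    return out


# ---------------------------------------------------------------------------
# quality optimization
# ---------------------------------------------------------------------------


def _node_adjacency(n_nodes, quads):
    nb = [set() for _ in range(n_nodes)]
    e = quad_edges(quads).reshape(-1, 2)
    for a, b in e:
        nb[a].add(int(b))
        nb[b].add(int(a))
    return nb


def optimize_quality(
    sheet: HexSheet,
    sj_target: float,
    max_iterations: int = 200,
    surface=None,
    lam: float = 0.4,
) -> HexSheet:
    """Constrained Laplacian smoothing until min SJ >= target.

    Interior nodes relax toward their quad-neighbour mean; boundary
    nodes relax along the boundary loop only; every move is re-projected
    onto the source cartilage surface. An iteration is accepted only if
    the number of elements below target does not increase (monotone
    acceptance); the loop is hard-capped at ``max_iterations``.
    """
    out = sheet.copy()
    sj = out.scaled_jacobians()
    bad = int((sj < sj_target).sum())
    if bad == 0:
        return out

    bq = out.bone_quads()
    nb_bone = _node_adjacency(len(out.nodes), bq)
    edges = quad_edges(bq).reshape(-1, 2)
    key, counts = np.unique(np.sort(edges, axis=1), axis=0, return_counts=True)
    rim_edges = key[counts == 1]
    rim_nodes = set(np.unique(rim_edges).tolist())
    rim_nb = {v: set() for v in rim_nodes}
    for a, b in rim_edges:
        rim_nb[int(a)].add(int(b))
        rim_nb[int(b)].add(int(a))

    prox = None
    if surface is not None:
        prox = MeshProximity(
            surface.vertices.view(np.ndarray), surface.faces.view(np.ndarray)
        )

    bone_ids = np.nonzero(out.is_bone)[0]

    def smooth_once(nodes, step, subset=None):
        new = nodes.copy()
        targets = bone_ids if subset is None else [v for v in bone_ids if int(v) in subset]
        moved = []
        for v in targets:
            neigh = rim_nb.get(int(v)) if int(v) in rim_nodes else nb_bone[int(v)]
            if not neigh:
                continue
            nlist = list(neigh)
            mean_b = nodes[nlist].mean(axis=0)
            mean_j = nodes[out.partner[nlist]].mean(axis=0)
            new[v] = (1 - step) * nodes[v] + step * mean_b
            pj = out.partner[v]
            new[pj] = (1 - step) * nodes[pj] + step * mean_j
            moved.extend([int(v), int(pj)])
        if prox is not None and moved:
            snapped, _, _ = prox.query(new[moved])
            new[moved] = snapped
        return new

    def bad_node_set(sj_vals):
        elems = np.nonzero(sj_vals < sj_target)[0]
        ns = set(int(x) for x in out.hexes[elems].ravel())
        # include the 1-ring
        ring = set()
        for v in list(ns):
            if out.is_bone[v]:
                ring.update(nb_bone[v])
        return ns | ring

    step = lam
    min_sj = float(sj.min())
    stall = 0
    for it in range(max_iterations):
        # alternate a global gentle pass with a targeted local pass on
        # the below-target elements and their 1-ring
        cand = out.copy()
        if it % 2 == 0:
            cand.nodes = smooth_once(out.nodes, step)
        else:
            cand.nodes = smooth_once(out.nodes, min(2 * step, 0.9), bad_node_set(out.scaled_jacobians()))
        sj_c = cand.scaled_jacobians()
        bad_c = int((sj_c < sj_target).sum())
        min_c = float(sj_c.min())
        improved = bad_c < bad or (bad_c == bad and min_c > min_sj + 1e-12)
        if bad_c <= bad and improved:
            out, bad, min_sj = cand, bad_c, min_c
            stall = 0
            if bad == 0:
                return out
        else:
            step *= 0.5
            stall += 1
            if step < 1e-4:
                step = lam  # restart the step schedule once
            if stall > 24:
                break
    sj = out.scaled_jacobians()
    worst = np.argsort(sj)[:5]
    raise QualityError(
        f"optimization stalled at {bad} elements below SJ {sj_target} "
        f"(worst: {[(int(i), float(sj[i])) for i in worst]})",
        worst=[(int(i), float(sj[i])) for i in worst],
    )


# ---------------------------------------------------------------------------
# subdivision
# ---------------------------------------------------------------------------


def subdivide_inplane(sheet: HexSheet, surface=None) -> HexSheet:
    """Split every element 2x2 in-plane (never depth-wise).

    Midpoint nodes are shared through sorted-edge keys so conformity is
    preserved; original corner nodes keep their coordinates. New nodes
    are re-projected onto the cartilage surface when given.
    """
    nodes = [sheet.nodes.copy()]
    partner = list(sheet.partner)
    is_bone = list(sheet.is_bone)
    n0 = len(sheet.nodes)
    next_id = n0
    cache: dict = {}
    created = []

    def midpoint(ids):
        """Create (or reuse) the bone+joint node pair at the mean of
        bone-side node ids ``ids``; returns the bone node id."""
        nonlocal next_id
        key = tuple(sorted(ids))
        if key in cache:
            return cache[key]
        bpos = sheet.nodes[list(ids)].mean(axis=0)
        jpos = sheet.nodes[[sheet.partner[i] for i in ids]].mean(axis=0)
        b_id, j_id = next_id, next_id + 1
        next_id += 2
        created.extend([bpos, jpos])
        partner.extend([j_id, b_id])
        is_bone.extend([True, False])
        cache[key] = b_id
        return b_id

    new_hexes = []
    for e in sheet.hexes:
        b = e[:4]
        mids = [midpoint((int(b[k]), int(b[(k + 1) % 4]))) for k in range(4)]
        ctr = midpoint(tuple(int(x) for x in b))
        corner_loops = [
            [int(b[0]), mids[0], ctr, mids[3]],
            [mids[0], int(b[1]), mids[1], ctr],
            [ctr, mids[1], int(b[2]), mids[2]],
            [mids[3], ctr, mids[2], int(b[3])],
        ]
        for loop in corner_loops:
            new_hexes.append(loop + [partner[x] for x in loop])

    if created:
        nodes.append(np.asarray(created))
    all_nodes = np.concatenate(nodes)
    partner = np.asarray(partner)
    is_bone = np.asarray(is_bone)
    if surface is not None:
        prox = MeshProximity(
            surface.vertices.view(np.ndarray), surface.faces.view(np.ndarray)
        )
        new_ids = np.arange(n0, len(all_nodes))
        if len(new_ids):
            snapped, _, _ = prox.query(all_nodes[new_ids])
            all_nodes[new_ids] = snapped
    return HexSheet(
        all_nodes, np.asarray(new_hexes, dtype=np.int64), partner, is_bone, [], sheet.grid
    )


def subdivide_depth(sheet: HexSheet, layers: int = 4) -> HexMesh:
    """Split the sheet into ``layers`` linearly spaced depth layers."""
    if layers < 1:
        raise ValueError("layers must be >= 1")
    bone_ids = np.nonzero(sheet.is_bone)[0]
    col_of = np.full(len(sheet.nodes), -1, dtype=np.int64)
    col_of[bone_ids] = np.arange(len(bone_ids))
    col_of[sheet.partner[bone_ids]] = np.arange(len(bone_ids))
    P = len(bone_ids)
    b = sheet.nodes[bone_ids]
    j = sheet.nodes[sheet.partner[bone_ids]]
    # node (c, l) -> id c + l*P ; l=0 bone side, l=layers joint side
    frac = np.linspace(0.0, 1.0, layers + 1)
    nodes = np.concatenate([(1 - f) * b + f * j for f in frac])

    hexes = []
    layer_of = []
    for e in sheet.hexes:
        cols = col_of[e[:4]]
        for l in range(layers):
            bottom = cols + l * P
            top = cols + (l + 1) * P
            hexes.append(np.concatenate([bottom, top]))
            layer_of.append(l)
    return HexMesh(
        nodes,
        np.asarray(hexes, dtype=np.int64),
        layers,
        np.asarray(layer_of, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# statistics helpers
# ---------------------------------------------------------------------------


def inplane_edge_lengths(mesh_or_sheet) -> np.ndarray:
    """Lengths of all in-plane (non-depth) element edges."""
    if isinstance(mesh_or_sheet, HexSheet):
        nodes = mesh_or_sheet.nodes
        quads = np.concatenate(
            [mesh_or_sheet.bone_quads(), mesh_or_sheet.joint_quads()]
        )
    else:
        nodes = mesh_or_sheet.nodes
        quads = np.concatenate(
            [hex_faces(mesh_or_sheet.hexes)[:, 0], hex_faces(mesh_or_sheet.hexes)[:, 1]]
        )
    e = np.unique(np.sort(quad_edges(quads).reshape(-1, 2), axis=1), axis=0)
    return np.linalg.norm(nodes[e[:, 0]] - nodes[e[:, 1]], axis=1)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

_FALLBACK_SEQUENCE = (
    "disable_bone_fusion",
    "reduce_blend_displacement",
    "tibial_simplified_grid",
    "early_inplane_subdivision",
)


def _single_attempt(cart, site, bone_surface, params: MeshParams, options):
    from . import blend as blend_mod

    sp = params.sweep
    grid = make_sweep_grid(
        cart,
        site,
        target_edge_mm=sp.target_edge_mm,
        strategy=options.get("strategy"),
        params=sp,
        bone_hint=(bone_surface.vertices.view(np.ndarray).mean(axis=0)
                   if bone_surface is not None else None),
    )
    sheet = build_hex_sheet(grid)
    records = classify_degenerates(sheet)
    sheet = repair_degenerates(sheet, records, surface=cart)
    sheet = trim_boundary_slivers(sheet)

    def optimize_with_rescue(s, target):
        """Optimize; on a stall, trim boundary-touching stuck elements
        (slivers no node movement can fix) and retry."""
        for _ in range(4):
            try:
                return optimize_quality(s, target, sp.max_iterations, surface=cart)
            except QualityError:
                rim = set(int(v) for v in s.boundary_nodes())
                sj = s.scaled_jacobians()
                drop = np.array(
                    [
                        sj[k] < target and bool(set(map(int, e[:4])) & rim)
                        for k, e in enumerate(s.hexes)
                    ]
                )
                if not drop.any():
                    raise
                s = _rebuild_sheet(s, np.nonzero(~drop)[0])
        return optimize_quality(s, target, sp.max_iterations, surface=cart)

    if options.get("early_subdiv"):
        sheet = subdivide_inplane(sheet, surface=cart)
    sheet = optimize_with_rescue(sheet, sp.sj_stage1)
    if not options.get("early_subdiv"):
        sheet = subdivide_inplane(sheet, surface=cart)
    sheet = optimize_with_rescue(sheet, sp.sj_stage2)
    # rescue trimming may leave new pinches; clean once more pre-blend
    sheet = trim_boundary_slivers(sheet, sj_floor=0.0)
    sj_pre_blend = float(sheet.scaled_jacobians().min())

    blend_prov = {"fusion": "not_attempted", "applied": False}
    if params.blend.enabled:
        fuse_surface = bone_surface if options.get("fuse") else None
        sheet, blend_prov = blend_mod.blend_cartilage(
            sheet,
            fuse_surface,
            params.blend,
            magnitude_scale=options.get("blend_scale", 1.0),
        )
        blend_prov["applied"] = True
    mesh = subdivide_depth(sheet, sp.layers)
    mesh.provenance = {
        "site": site,
        "strategy": grid.strategy,
        "degenerate_records": [
            {"klass": r.klass, "elements": list(map(int, r.element_ids))}
            for r in records
        ],
        "sj_pre_blend_min": sj_pre_blend,
        "sj_final_min": float(mesh.scaled_jacobians().min()),
        "blend": blend_prov,
    }
    return mesh


def mesh_cartilage(
    cartilage_surface,
    site: str,
    bone_surface=None,
    params: MeshParams | None = None,
) -> HexMesh:
    """Mesh one cartilage tissue end to end, walking the fallback cascade.

    On failure the cascade cumulatively disables bone fusion, halves the
    blend displacement, switches the tibial grid to the simplified
    rectilinear strategy, and finally performs the in-plane subdivision
    early; fired fallbacks are recorded in provenance.
    """
    params = params or MeshParams()
    base = {
        "fuse": params.fuse_to_bone and bone_surface is not None,
        "blend_scale": 1.0,
        "strategy": None,
        "early_subdiv": False,
    }
    attempts = [([], dict(base))]
    applied = []
    opts = dict(base)
    for fb in _FALLBACK_SEQUENCE:
        opts = dict(opts)
        if fb == "disable_bone_fusion":
            if not base["fuse"]:
                continue
            opts["fuse"] = False
        elif fb == "reduce_blend_displacement":
            if not params.blend.enabled:
                continue
            opts["blend_scale"] = 0.5
        elif fb == "tibial_simplified_grid":
            if site != "tibial":
                continue
            opts["strategy"] = "rectilinear"
        elif fb == "early_inplane_subdivision":
            opts["early_subdiv"] = True
        applied = applied + [fb]
        attempts.append((list(applied), dict(opts)))

    failures = []
    for fired, options in attempts:
        try:
            mesh = _single_attempt(
                cartilage_surface, site, bone_surface, params, options
            )
            mesh.provenance["fallbacks"] = fired
            mesh.provenance["failures_before_success"] = failures
            return mesh
        except MeshingError as err:
            failures.append({"fallbacks": fired, "error": str(err)})
    raise MeshingError(
        "all fallbacks exhausted for "
        f"{site} cartilage; stage diagnostics: {failures}"
    )
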