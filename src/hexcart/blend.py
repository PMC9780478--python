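"""Cartilage-to-bone interface blending of the single-layer hex sheet.

An unblended sheet ends in a vertical brick wall at the cartilage edge,
which catches on articulating meshes during contact. Blending replaces
the wall with a ramp: bone-side edge nodes stretch outward along the
bone tangent (80% of the displacement budget), joint-side edge nodes
compress inward (20%), sized so the edge profile reaches a 45 deg slope.
If a bone surface is supplied, stretched bone-side nodes fuse to it via
nearest-surface search. Skew is controlled by relaxing bone-side
displacements in 10% decrements until every joint-side crease keeps a
minimum feature angle; fold-over at interior curves and holes is
resolved by Savitzky-Golay smoothing of the edge loops and, failing
that, global 10% magnitude reductions. A graduated advancing-front
Laplacian smoothing then fairs the bone- and joint-side surfaces, with
iteration counts halved at each front advance and the cartilage edge
nodes held fixed throughout. Geometry only: connectivity never changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import BlendError
from .geometry import MeshProximity, triangles_intersect
from .metrics import scaled_jacobian
from .params import BlendParams
from .hexsweep import HexSheet, quad_edges

_EPS = 1e-12


# ---------------------------------------------------------------------------
# edge topology
# ---------------------------------------------------------------------------


def _rim_loops(sheet: HexSheet):
    """Ordered closed loops of bone-side boundary node ids."""
    edges = quad_edges(sheet.bone_quads()).reshape(-1, 2)
    key, counts = np.unique(np.sort(edges, axis=1), axis=0, return_counts=True)
    rim = key[counts == 1]
    if len(rim) == 0:
        raise BlendError("sheet has no boundary: nothing to blend")
    nb: dict[int, list] = {}
    for a, b in rim:
        nb.setdefault(int(a), []).append(int(b))
        nb.setdefault(int(b), []).append(int(a))
    for v, ns in nb.items():
        if len(ns) != 2:
            raise BlendError(
                f"open edge-loop pairing mismatch at node {v} "
                f"({len(ns)} rim neighbours)"
            )
    loops = []
    visited = set()
    for start in sorted(nb):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        prev, cur = None, start
        while True:
            nxt = [x for x in nb[cur] if x != prev]
            nxt = nxt[0] if nxt else prev
            if nxt == start:
                break
            loop.append(nxt)
            visited.add(nxt)
            prev, cur = cur, nxt
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops, rim


def _node_depths(sheet: HexSheet) -> np.ndarray:
    """BFS hop distance of every bone-side node from the rim (rim = 0)."""
    from collections import deque

    bq = sheet.bone_quads()
    nbr: dict[int, set] = {}
    for a, b in quad_edges(bq).reshape(-1, 2):
        nbr.setdefault(int(a), set()).add(int(b))
        nbr.setdefault(int(b), set()).add(int(a))
    depth = np.full(len(sheet.nodes), -1, dtype=np.int64)
    loops, _ = _rim_loops(sheet)
    q = deque()
    for loop in loops:
        for v in loop:
            depth[v] = 0
            q.append(int(v))
    while q:
        v = q.popleft()
        for w in nbr.get(v, ()):
            if depth[w] < 0:
                depth[w] = depth[v] + 1
                q.append(w)
    # joint nodes inherit their partner's depth
    bone_ids = np.nonzero(sheet.is_bone)[0]
    depth[sheet.partner[bone_ids]] = depth[bone_ids]
    return depth


# ---------------------------------------------------------------------------
# displacement field
# ---------------------------------------------------------------------------


@dataclass
class BlendDisplacement:
    """Edge-node displacement field for one sheet."""

    bone_ids: np.ndarray       # (B,) rim node ids, bone side
    joint_ids: np.ndarray      # (B,) their joint-side partners
    bone_vecs: np.ndarray      # (B,3) full-magnitude bone-side vectors
    joint_vecs: np.ndarray     # (B,3) joint-side vectors
    depth: np.ndarray          # (B,) local cartilage depth (mm)
    relaxation: np.ndarray     # (B,) bone-side per-node level in [0,1]
    global_scale: float = 1.0
    loops: list = field(default_factory=list)  # index arrays into bone_ids
    fused: np.ndarray | None = None
    history: dict = field(default_factory=dict)

    @property
    def relaxation_level(self) -> float:
        return float(self.relaxation.mean()) * self.global_scale

    def bone_targets(self, sheet) -> np.ndarray:
        return (
            sheet.nodes[self.bone_ids]
            + self.global_scale * self.relaxation[:, None] * self.bone_vecs
        )

    def joint_targets(self, sheet) -> np.ndarray:
        return sheet.nodes[self.joint_ids] + self.global_scale * self.joint_vecs


def _wall_normals(sheet, loops):
    """Outward in-plane wall normal at each rim node (from wall quads)."""
    pos = sheet.nodes
    interior = pos[sheet.is_bone].mean(axis=0)
    normals = {v: np.zeros(3) for loop in loops for v in loop}
    for loop in loops:
        for k in range(len(loop)):
            a, b = int(loop[k]), int(loop[(k + 1) % len(loop)])
            pa, pb = pos[a], pos[b]
            ja, jb = pos[sheet.partner[a]], pos[sheet.partner[b]]
            n = np.cross(jb - pa, ja - pb)  # wall quad (a,b,jb,ja) diagonals
            if np.linalg.norm(n) < _EPS:
                continue
            if (0.25 * (pa + pb + ja + jb) - interior) @ n < 0:
                n = -n
            normals[a] += n
            normals[b] += n
    out = {}
    for v, n in normals.items():
        nn = np.linalg.norm(n)
        out[v] = n / nn if nn > _EPS else n
    return out


def init_blend_displacements(
    sheet: HexSheet,
    bone_surface=None,
    params: BlendParams | None = None,
    magnitude_scale: float = 1.0,
) -> BlendDisplacement:
    """Edge displacement field: 80/20 bone/joint split toward a 45 deg ramp.

    Per rim node the displacement budget is ``depth / tan(slope)``;
    the bone-side node stretches outward along the bone tangent by
    ``bone_share`` of the budget and the joint-side node compresses
    inward by the remainder. With a bone surface, stretched bone-side
    nodes snap to its nearest element surface (fusion) unless the
    nearest point is further than ``fusion_search_factor x depth``.
    """
    params = params or BlendParams()
    loops, _ = _rim_loops(sheet)
    bone_ids = np.concatenate(loops)
    offsets = np.cumsum([0] + [len(l) for l in loops])
    loop_idx = [np.arange(offsets[k], offsets[k + 1]) for k in range(len(loops))]
    joint_ids = sheet.partner[bone_ids]
    bpos = sheet.nodes[bone_ids]
    jpos = sheet.nodes[joint_ids]
    up = jpos - bpos
    depth = np.linalg.norm(up, axis=1)
    up = up / np.maximum(depth[:, None], _EPS)

    wall_n = _wall_normals(sheet, loops)
    wn = np.array([wall_n[int(v)] for v in bone_ids])
    # outward direction in the local bone tangent plane
    d_out = wn - np.einsum("ij,ij->i", wn, up)[:, None] * up
    d_out /= np.maximum(np.linalg.norm(d_out, axis=1, keepdims=True), _EPS)

    budget = depth / np.tan(np.deg2rad(params.slope_deg)) * magnitude_scale
    bone_vecs = params.bone_share * budget[:, None] * d_out
    joint_vecs = -(1.0 - params.bone_share) * budget[:, None] * d_out

    fused = np.zeros(len(bone_ids), dtype=bool)
    if bone_surface is not None:
        prox = MeshProximity(
            bone_surface.vertices.view(np.ndarray),
            bone_surface.faces.view(np.ndarray),
        )
        stretched = bpos + bone_vecs
        snapped, _, _ = prox.query(stretched)
        travel = np.linalg.norm(snapped - bpos, axis=1)
        ok = travel <= params.fusion_search_factor * np.maximum(depth, _EPS)
        bone_vecs[ok] = snapped[ok] - bpos[ok]
        fused = ok

    return BlendDisplacement(
        bone_ids=bone_ids,
        joint_ids=joint_ids,
        bone_vecs=bone_vecs,
        joint_vecs=joint_vecs,
        depth=depth,
        relaxation=np.ones(len(bone_ids)),
        loops=loop_idx,
        fused=fused,
    )


# ---------------------------------------------------------------------------
# feature-angle enforcement
# ---------------------------------------------------------------------------


def _applied_nodes(sheet, disp):
    nodes = sheet.nodes.copy()
    nodes[disp.bone_ids] = disp.bone_targets(sheet)
    nodes[disp.joint_ids] = disp.joint_targets(sheet)
    return nodes


def _joint_crease_angles(sheet, disp, nodes):
    """Feature angle at each joint-side rim edge between the interior
    joint-surface quad and the (displaced) wall quad. Returns per-edge
    angles and the rim-node pairs (indices into disp arrays)."""
    pos_of = {int(v): k for k, v in enumerate(disp.bone_ids)}
    jq = sheet.joint_quads()
    # joint quad adjacent to each joint rim edge
    edge_owner = {}
    for qi, q in enumerate(jq):
        for k in range(4):
            a, b = int(q[k]), int(q[(k + 1) % 4])
            edge_owner.setdefault((min(a, b), max(a, b)), []).append(qi)
    angles, pairs = [], []
    for loop in disp.loops:
        n = len(loop)
        for k in range(n):
            i1, i2 = int(loop[k]), int(loop[(k + 1) % n])
            a = int(disp.bone_ids[i1])
            b = int(disp.bone_ids[i2])
            ja = int(disp.joint_ids[i1])
            jb = int(disp.joint_ids[i2])
            owners = edge_owner.get((min(ja, jb), max(ja, jb)), [])
            if len(owners) != 1:
                continue  # not a rim edge of the joint surface
            q = jq[owners[0]]
            p = nodes[q]
            n_surf = np.cross(p[2] - p[0], p[3] - p[1])
            n_surf /= max(np.linalg.norm(n_surf), _EPS)
            w = nodes[[a, b, jb, ja]]
            n_wall = np.cross(w[2] - w[0], w[3] - w[1])
            n_wall /= max(np.linalg.norm(n_wall), _EPS)
            ang = np.degrees(np.arccos(np.clip(abs(n_surf @ n_wall), -1, 1)))
            angles.append(ang)
            pairs.append((i1, i2))
    return np.asarray(angles), pairs


def enforce_min_feature_angle(
    sheet: HexSheet,
    disp: BlendDisplacement,
    min_angle_deg: float | None = None,
    params: BlendParams | None = None,
) -> BlendDisplacement:
    """Relax bone-side displacements until joint-side creases are steep
    enough.

    Nodes adjacent to a violating crease lose ``relax_step`` (10%) of
    their initial bone-side magnitude per iteration; levels are monotone
    non-increasing and floored at zero (vertical wall), where the crease
    is maximally steep, so termination is guaranteed.
    """
    params = params or BlendParams()
    if min_angle_deg is None:
        min_angle_deg = params.min_feature_angle_deg
    levels = [disp.relaxation.copy()]
    for _ in range(int(np.ceil(1.0 / params.relax_step)) + 1):
        nodes = _applied_nodes(sheet, disp)
        angles, pairs = _joint_crease_angles(sheet, disp, nodes)
        if len(angles) == 0 or angles.min() >= min_angle_deg:
            break
        bad = angles < min_angle_deg
        relax = disp.relaxation.copy()
        for (i1, i2), isbad in zip(pairs, bad):
            if isbad:
                relax[i1] = max(0.0, relax[i1] - params.relax_step)
                relax[i2] = max(0.0, relax[i2] - params.relax_step)
        if np.allclose(relax, disp.relaxation):
            break
        disp.relaxation = relax
        levels.append(relax.copy())
    disp.history["relaxation_levels"] = [float(l.mean()) for l in levels]
    return disp


# ---------------------------------------------------------------------------
# intersection resolution
# ---------------------------------------------------------------------------


def _edge_region_triangles(sheet, disp, nodes):
    """Triangulated faces of all rim-adjacent elements (walls + caps)."""
    rim = set(int(v) for v in disp.bone_ids) | set(int(v) for v in disp.joint_ids)
    tris = []
    owner = []
    from .hexsweep import hex_faces

    faces = hex_faces(sheet.hexes)
    for ei, ef in enumerate(faces):
        if not (set(sheet.hexes[ei].tolist()) & rim):
            continue
        for f in ef:
            tris.append([f[0], f[1], f[2]])
            tris.append([f[0], f[2], f[3]])
            owner.append(ei)
            owner.append(ei)
    tri_idx = np.asarray(tris, dtype=np.int64)
    return nodes[tri_idx], tri_idx, np.asarray(owner)


def _count_intersections(tri_pts, tri_idx):
    """Number of intersecting face-triangle pairs (AABB prefilter,
    node-sharing pairs excluded)."""
    lo = tri_pts.min(axis=1)
    hi = tri_pts.max(axis=1)
    n = len(tri_pts)
    order = np.argsort(lo[:, 0])
    count = 0
    pairs_a, pairs_b = [], []
    for ii in range(n):
        i = order[ii]
        for jj in range(ii + 1, n):
            j = order[jj]
            if lo[j, 0] > hi[i, 0]:
                break
            if (lo[j] > hi[i]).any() or (lo[i] > hi[j]).any():
                continue
            if set(tri_idx[i]) & set(tri_idx[j]):
                continue
            pairs_a.append(i)
            pairs_b.append(j)
    if not pairs_a:
        return 0
    hits = triangles_intersect(tri_pts[pairs_a], tri_pts[pairs_b])
    return int(hits.sum())


def resolve_intersections(
    sheet: HexSheet,
    disp: BlendDisplacement,
    params: BlendParams | None = None,
) -> BlendDisplacement:
    """Savitzky-Golay smoothing of edge loops, then global 10% backoff.

    Displaced edge-node coordinates are filtered component-wise along
    each closed loop (degree-3 polynomial, periodic padding), exactly
    preserving locally-cubic edge curves. If element faces in the edge
    region still intersect, all displacement magnitudes shrink by 10%
    per round; reaching zero magnitude with intersections raises
    :class:`BlendError`.
    """
    params = params or BlendParams()
    window = params.sg_window
    if window % 2 == 0:
        window += 1

    # smooth the *displaced* edge positions loop-wise and fold the
    # correction back into the vectors
    bone_t = disp.bone_targets(sheet)
    joint_t = disp.joint_targets(sheet)
    scale = max(disp.global_scale, _EPS)
    for idx in disp.loops:
        if len(idx) <= window:
            continue
        for arr, ids, vecs, base in (
            (bone_t, disp.bone_ids, disp.bone_vecs, disp.relaxation),
            (joint_t, disp.joint_ids, disp.joint_vecs, None),
        ):
            sm = savgol_filter(
                arr[idx], window_length=window, polyorder=params.sg_degree,
                axis=0, mode="wrap",
            )
            delta = sm - arr[idx]
            if base is None:
                vecs[idx] += delta / scale
            else:
                eff = np.maximum(base[idx], 0.1)[:, None] * scale
                vecs[idx] += delta / eff
    retries = 0
    while True:
        nodes = _applied_nodes(sheet, disp)
        tri_pts, tri_idx, _ = _edge_region_triangles(sheet, disp, nodes)
        n_bad = _count_intersections(tri_pts, tri_idx)
        if n_bad == 0:
            break
        if disp.global_scale < 1e-3:
            raise BlendError(
                f"{n_bad} intersecting element-face pairs persist at zero "
                "blend magnitude"
            )
        disp.global_scale *= params.intersect_relax_factor
        retries += 1
    disp.history["intersection_retries"] = retries
    return disp


# ---------------------------------------------------------------------------
# graduated advancing-front smoothing
# ---------------------------------------------------------------------------


def _front_iterations(n_surface, n_front, params):
    if n_surface <= n_front:
        return params.smoothing_iter_cap
    n0 = params.smoothing_iter_scale * n_surface / (n_surface - n_front)
    return int(min(np.ceil(n0), params.smoothing_iter_cap))


def _laplacian_band(nodes, adjacency, movable, iterations, lam=0.5):
    V = nodes.copy()
    movable = np.asarray(sorted(movable), dtype=np.int64)
    if len(movable) == 0:
        return V
    nb_list = [np.asarray(sorted(adjacency[int(v)]), dtype=np.int64) for v in movable]
    for _ in range(iterations):
        means = np.array([V[nb].mean(axis=0) for nb in nb_list])
        V[movable] = (1 - lam) * V[movable] + lam * means
    return V


def graduated_front_smoothing(
    sheet: HexSheet, params: BlendParams | None = None
) -> HexSheet:
    """Advancing-front Laplacian fairing of the blended edge region.

    Bone side: fronts at element depths 2..5 with the empirical initial
    iteration count ``550 n_surf / (n_surf - n_front)`` (capped), halved
    at each advance. Joint side: one front, full initial count, stopped
    early if the blended crease angle falls to the 30 deg stop or any
    quality gate (interior SJ > 0.5, blended SJ > 0) would be violated.
    Cartilage edge nodes never move, nor does anything beyond the fifth
    edgewise layer.
    """
    params = params or BlendParams()
    out = sheet.copy()
    depth = _node_depths(out)
    sj0 = out.scaled_jacobians()
    elem_depth = depth[out.hexes].min(axis=1)
    blended_elems = elem_depth <= 1
    interior_elems = ~blended_elems

    def gates_ok(s):
        sj = s.scaled_jacobians()
        if blended_elems.any() and sj[blended_elems].min() <= 0:
            return False
        if interior_elems.any():
            # interior gate: SJ > 0.5, but never demand more than the
            # incoming mesh achieved
            floor = min(0.5, sj0[interior_elems].min() - 1e-9)
            if sj[interior_elems].min() < floor:
                return False
        return True

    for side in ("bone", "joint"):
        quads = out.bone_quads() if side == "bone" else out.joint_quads()
        qdepth = depth[quads].min(axis=1) + 1  # faces touching rim: depth 1
        n_surface = len(quads)
        adjacency: dict[int, set] = {}
        for a, b in quad_edges(quads).reshape(-1, 2):
            adjacency.setdefault(int(a), set()).add(int(b))
            adjacency.setdefault(int(b), set()).add(int(a))

        if side == "bone":
            iters = None
            for front_d in params.bone_front_depths:
                sel = qdepth <= front_d
                n_front = int(sel.sum())
                if n_front == 0:
                    continue
                if iters is None:
                    iters = _front_iterations(n_surface, n_front, params)
                else:
                    iters = int(np.ceil(iters / 2))
                movable = set(
                    int(v)
                    for v in np.unique(quads[sel])
                    if 1 <= depth[v] <= params.max_moving_node_depth
                )
                cand = out.copy()
                cand.nodes = _laplacian_band(out.nodes, adjacency, movable, iters)
                if gates_ok(cand):
                    out = cand
                else:
                    break
        else:
            sel = qdepth <= params.joint_front_depth
            n_front = int(sel.sum())
            if n_front == 0:
                continue
            iters = _front_iterations(n_surface, n_front, params)
            movable = set(
                int(v)
                for v in np.unique(quads[sel])
                if 1 <= depth[v] <= params.max_moving_node_depth
            )
            chunk = 10
            done = 0
            while done < iters:
                step = min(chunk, iters - done)
                cand = out.copy()
                cand.nodes = _laplacian_band(out.nodes, adjacency, movable, step)
                # stop before elements skew or the crease hits the stop angle
                if not gates_ok(cand):
                    break
                disp_stub = _rim_displacement_stub(cand)
                angles, _ = _joint_crease_angles(cand, disp_stub, cand.nodes)
                if len(angles) and angles.min() <= params.joint_stop_angle_deg:
                    break
                out = cand
                done += step
    return out


def _rim_displacement_stub(sheet):
    """Zero-magnitude displacement over the rim, for angle evaluation."""
    loops, _ = _rim_loops(sheet)
    bone_ids = np.concatenate(loops)
    offsets = np.cumsum([0] + [len(l) for l in loops])
    return BlendDisplacement(
        bone_ids=bone_ids,
        joint_ids=sheet.partner[bone_ids],
        bone_vecs=np.zeros((len(bone_ids), 3)),
        joint_vecs=np.zeros((len(bone_ids), 3)),
        depth=np.zeros(len(bone_ids)),
        relaxation=np.ones(len(bone_ids)),
        loops=[np.arange(offsets[k], offsets[k + 1]) for k in range(len(loops))],
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def blend_cartilage(
    sheet: HexSheet,
    bone_surface=None,
    params: BlendParams | None = None,
    magnitude_scale: float = 1.0,
):
    """Run the full blending chain; returns ``(sheet, provenance)``.

    Node and element counts are unchanged (geometry-only operation).
    Provenance records the fusion tier: ``full`` (every bone-side edge
    node fused), ``perimeter`` (outer loop fused, interior hole loops
    not), or ``unfused``.
    """
    params = params or BlendParams()
    disp = init_blend_displacements(sheet, bone_surface, params, magnitude_scale)
    disp = enforce_min_feature_angle(sheet, disp, params=params)
    disp = resolve_intersections(sheet, disp, params=params)

    depth = _node_depths(sheet)
    blended = depth[sheet.hexes].min(axis=1) <= 1

    def build(d):
        s = sheet.copy()
        s.nodes = _applied_nodes(sheet, d)
        return s

    # the applied displacement itself must keep blended elements valid;
    # back off globally in 10% steps if it does not
    out = build(disp)
    while blended.any() and out.scaled_jacobians()[blended].min() <= 0:
        if disp.global_scale < 0.2:
            break
        disp.global_scale *= params.intersect_relax_factor
        out = build(disp)
    out = graduated_front_smoothing(out, params)

    sj = out.scaled_jacobians()
    if blended.any() and sj[blended].min() <= 0:
        raise BlendError(
            f"blended elements degenerate (min SJ {sj[blended].min():.3f})"
        )

    if bone_surface is None or disp.fused is None:
        tier = "unfused"
    elif disp.fused.all():
        tier = "full"
    else:
        # outer loop = loop with the largest bounding box
        extents = [
            np.ptp(sheet.nodes[disp.bone_ids[idx]], axis=0).max()
            for idx in disp.loops
        ]
        outer = disp.loops[int(np.argmax(extents))]
        tier = "perimeter" if disp.fused[outer].all() else "unfused"
    prov = {
        "fusion": tier,
        "n_edge_nodes": int(len(disp.bone_ids)),
        "n_fused": int(disp.fused.sum()) if disp.fused is not None else 0,
        "relaxation_level": disp.relaxation_level,
        "history": disp.history,
    }
    return out, prov
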