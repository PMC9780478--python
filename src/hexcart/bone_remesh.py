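"""Uniform isotropic triangular remeshing of bone surfaces.

Voronoi-clustering remeshing: the input surface is refined to a dense
sample, samples are partitioned into approximately equal-area clusters
(area-weighted k-means, the discrete analogue of centroidal Voronoi
tessellation), and the cluster adjacency graph is triangulated. Cluster
count is chosen so an equilateral tiling of the surface area at the
target edge length has one vertex per cluster:

    n_clusters = round(2 * A / (sqrt(3) * target^2))

which makes the mean output edge length track the target. Bones are
rigid shells in downstream simulations, so only the surface is meshed.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .geometry import MeshProximity, edge_lengths


class RemeshError(RuntimeError):
    pass


def _drop_overused_edges(faces, verts):
    """Remove the smallest faces on edges used by more than two faces."""
    faces = list(map(tuple, faces))
    changed = True
    while changed:
        changed = False
        use: dict = {}
        for fi, f in enumerate(faces):
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                use.setdefault((min(a, b), max(a, b)), []).append(fi)
        for edge, owners in use.items():
            if len(owners) <= 2:
                continue
            areas = []
            for fi in owners:
                p = verts[list(faces[fi])]
                areas.append(0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0])))
            order = np.argsort(areas)
            for k in order[: len(owners) - 2]:
                faces[owners[k]] = None
            faces = [f for f in faces if f is not None]
            changed = True
            break
    return np.asarray(faces, dtype=np.int64)


def remesh_uniform(
    surface: trimesh.Trimesh,
    target_edge_mm: float = 3.0,
    seed: int = 0,
    oversample: float = 30.0,
) -> trimesh.Trimesh:
    """Isotropic Voronoi-clustering remesh with mean edge ~ target.

    Deterministic for a fixed ``seed``: the fine sampling, the k-means
    initialization and the retry schedule (sampling density doubles on a
    non-manifold cluster adjacency) are all seed-derived. Raises
    :class:`RemeshError` when the target is too large for the surface
    (fewer than ~12 clusters or larger than the smallest bounding-box
    extent).
    """
    if not surface.is_watertight:
        raise RemeshError("remesh_uniform requires a watertight input surface")
    area = float(surface.area)
    n_clusters = int(round(2.0 * area / (np.sqrt(3.0) * target_edge_mm**2)))
    extent = surface.extents.min()
    if n_clusters < 12 or target_edge_mm > extent:
        raise RemeshError(
            f"target edge {target_edge_mm} mm too large for surface "
            f"(area {area:.1f} mm^2, min extent {extent:.1f} mm)"
        )
    last_err = None
    for attempt in range(3):
        try:
            return _remesh_once(
                surface, n_clusters, seed + attempt, oversample * 2**attempt
            )
        except RemeshError as err:
            last_err = err
    raise last_err


def _farthest_point_seeds(centers, k, start):
    seeds = [int(start)]
    d = np.linalg.norm(centers - centers[start], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        seeds.append(nxt)
        d = np.minimum(d, np.linalg.norm(centers - centers[nxt], axis=1))
    return np.asarray(seeds)


def _watershed_assign(centers, neighbors, seeds, centroids):
    """Multi-source region growing: connected Voronoi-like face clusters."""
    import heapq

    labels = np.full(len(centers), -1, dtype=np.int64)
    heap = []
    for k, f in enumerate(seeds):
        heapq.heappush(heap, (0.0, int(f), k))
    while heap:
        d, f, k = heapq.heappop(heap)
        if labels[f] >= 0:
            continue
        labels[f] = k
        for nb in neighbors[f]:
            if labels[nb] < 0:
                heapq.heappush(
                    heap, (float(np.linalg.norm(centers[nb] - centroids[k])), int(nb), k)
                )
    return labels


def _vertex_face_ring(vF, v, edge_faces, F):
    """Incident faces of vertex v in cyclic order (closed manifold)."""
    start = vF[0]
    ring = [start]
    # entering edge: pick one of the two v-edges of the start face
    f = start
    corner = list(F[f]).index(v)
    b = F[f][(corner + 1) % 3]
    while True:
        pair = edge_faces.get((min(v, b), max(v, b)))
        if pair is None or len(pair) != 2:
            return None  # boundary or non-manifold: no closed ring
        nxt = pair[0] if pair[1] == f else pair[1]
        if nxt == start:
            break
        ring.append(nxt)
        f = nxt
        others = [x for x in F[f] if x != v and x != b]
        if len(others) != 1:
            return None
        b = others[0]
        if len(ring) > len(vF):
            return None
    return ring


def _remesh_once(surface, n_clusters, seed, oversample):
    # refine until there are enough samples per cluster for a stable
    # discrete clustering
    V = surface.vertices.view(np.ndarray).copy()
    F = surface.faces.view(np.ndarray).copy()
    for _ in range(10):
        if len(F) >= oversample * n_clusters:
            break
        V, F = trimesh.remesh.subdivide(V, F)
    tri = V[F]
    centers = tri.mean(axis=1)
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    fine = trimesh.Trimesh(V, F, process=False)
    neighbors = [[] for _ in range(len(F))]
    for a, b in fine.face_adjacency:
        neighbors[a].append(int(b))
        neighbors[b].append(int(a))

    # centroidal Voronoi iteration with connectivity-preserving
    # (watershed) assignment: clusters are connected face regions, so
    # the dual triangulation stays manifold even on thin plates
    rng = np.random.default_rng(int(seed) % (2**31))
    seeds = _farthest_point_seeds(centers, n_clusters, rng.integers(len(F)))
    centroids = centers[seeds]
    labels = None
    for _ in range(8):
        labels = _watershed_assign(centers, neighbors, seeds, centroids)
        new_centroids = np.zeros((n_clusters, 3))
        wsum = np.zeros(n_clusters)
        np.add.at(new_centroids, labels, centers * areas[:, None])
        np.add.at(wsum, labels, areas)
        new_centroids /= np.maximum(wsum, 1e-300)[:, None]
        new_seeds = seeds.copy()
        for k in range(n_clusters):
            members = np.nonzero(labels == k)[0]
            if len(members):
                new_seeds[k] = members[
                    np.argmin(np.linalg.norm(centers[members] - new_centroids[k], axis=1))
                ]
        if np.array_equal(new_seeds, seeds):
            centroids = new_centroids
            break
        seeds, centroids = new_seeds, new_centroids
    labels = _watershed_assign(centers, neighbors, seeds, centroids)

    # dual triangulation: walk the ordered face ring of each fine vertex;
    # every maximal run of distinct cluster labels >= 3 contributes a fan
    edge_faces: dict = {}
    for fi, f in enumerate(F):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edge_faces.setdefault((min(a, b), max(a, b)), []).append(fi)
    vert_faces = [[] for _ in range(len(V))]
    for fi, f in enumerate(F):
        for c in f:
            vert_faces[c].append(fi)
    tri_set = {}
    out_faces = []
    for v in range(len(V)):
        if not vert_faces[v]:
            continue
        ring = _vertex_face_ring(vert_faces[v], v, edge_faces, F)
        if ring is None:
            continue
        labs = [int(labels[f]) for f in ring]
        dedup = [labs[0]]
        for l in labs[1:]:
            if l != dedup[-1]:
                dedup.append(l)
        if len(dedup) > 1 and dedup[-1] == dedup[0]:
            dedup.pop()
        if len(dedup) < 3 or len(set(dedup)) != len(dedup):
            continue
        for a, b in zip(dedup[1:-1], dedup[2:]):
            t = (dedup[0], a, b)
            key = tuple(sorted(t))
            if key not in tri_set:
                tri_set[key] = t
                out_faces.append(t)
    out_faces = np.asarray(out_faces, dtype=np.int64)
    if len(out_faces) < 4:
        raise RemeshError("cluster dual produced too few triangles")

    # cluster centroids, projected back onto the source surface
    prox = MeshProximity(surface.vertices.view(np.ndarray), surface.faces.view(np.ndarray))
    out_verts, _, _ = prox.query(centroids)

    out_faces = _drop_overused_edges(out_faces, out_verts)
    out = trimesh.Trimesh(vertices=out_verts, faces=out_faces, process=False)
    out.update_faces(out.nondegenerate_faces())
    out.remove_unreferenced_vertices()
    trimesh.repair.fix_normals(out)
    if not out.is_watertight:
        trimesh.repair.fill_holes(out)
        trimesh.repair.fix_normals(out)
    if not out.is_watertight:
        raise RemeshError(
            "clustered remesh is not watertight; increase oversample or "
            "reduce target edge"
        )
    if out.volume < 0:
        out.invert()
    return out


def mean_edge_length(surface: trimesh.Trimesh) -> float:
    return float(
        edge_lengths(surface.vertices.view(np.ndarray), surface.faces.view(np.ndarray)).mean()
    )
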