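"""Quadric error-metric edge-collapse decimation.

Classic Garland-Heckbert simplification: each vertex carries the sum of
the (area-weighted) squared-plane-distance quadrics of its incident
faces; edges collapse in order of minimum quadric error at the optimal
contraction point, with manifold-link and normal-flip guards. Boundary
edges are pinned with perpendicular constraint planes so open rims do
not erode.
"""

from __future__ import annotations

import heapq

import numpy as np

_BOUNDARY_WEIGHT = 1e3


def _face_quadrics(vertices, faces):
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    n = np.cross(v1 - v0, v2 - v0)
    area2 = np.linalg.norm(n, axis=1)
    n_unit = n / np.maximum(area2[:, None], 1e-300)
    d = -np.einsum("ij,ij->i", n_unit, v0)
    p = np.concatenate([n_unit, d[:, None]], axis=1)  # (F,4)
    K = p[:, :, None] * p[:, None, :]
    return K * (0.5 * area2)[:, None, None]


def _optimal_point(Q, p1, p2):
    A = Q[:3, :3]
    b = -Q[:3, 3]
    candidates = []
    try:
        x = np.linalg.solve(A + 1e-9 * np.eye(3), b)
        candidates.append(x)
    except np.linalg.LinAlgError:
        pass
    candidates += [0.5 * (p1 + p2), p1, p2]
    best, best_cost = None, np.inf
    for x in candidates:
        h = np.append(x, 1.0)
        cost = float(h @ Q @ h)
        if cost < best_cost:
            best, best_cost = x, cost
    return best, max(best_cost, 0.0)


def decimate_quadric(vertices, faces, target_faces: int):
    """Collapse edges until ``target_faces`` remain; returns (V', F')."""
    V = np.array(vertices, dtype=float)
    F = np.array(faces, dtype=np.int64)
    n_faces = len(F)
    if target_faces >= n_faces:
        return V, F
    target_faces = max(target_faces, 4)

    K = _face_quadrics(V, F)
    Q = np.zeros((len(V), 4, 4))
    for c in range(3):
        np.add.at(Q, F[:, c], K)

    # boundary constraint quadrics
    edges_all = np.sort(
        np.concatenate([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges_all, axis=0, return_counts=True)
    fn = np.cross(V[F[:, 1]] - V[F[:, 0]], V[F[:, 2]] - V[F[:, 0]])
    if np.any(counts == 1):
        edge_face = {}
        for fi, f in enumerate(F):
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                edge_face.setdefault((min(a, b), max(a, b)), []).append(fi)
        for (a, b) in map(tuple, uniq[counts == 1]):
            fi = edge_face[(a, b)][0]
            e = V[b] - V[a]
            n = np.cross(e, fn[fi])
            nn = np.linalg.norm(n)
            if nn < 1e-12:
                continue
            n = n / nn
            p = np.append(n, -n @ V[a])
            Kb = _BOUNDARY_WEIGHT * np.outer(p, p) * np.linalg.norm(e)
            Q[a] += Kb
            Q[b] += Kb

    vertex_faces = [set() for _ in range(len(V))]
    for fi, f in enumerate(F):
        for c in f:
            vertex_faces[c].add(fi)
    face_alive = np.ones(n_faces, dtype=bool)
    alive = np.ones(len(V), dtype=bool)
    version = np.zeros(len(V), dtype=np.int64)

    heap = []

    def push_edge(a, b):
        a, b = (a, b) if a < b else (b, a)
        x, cost = _optimal_point(Q[a] + Q[b], V[a], V[b])
        heapq.heappush(heap, (cost, int(version[a]), int(version[b]), a, b, x))

    for a, b in uniq:
        push_edge(int(a), int(b))

    def neighbors(v):
        out = set()
        for fi in vertex_faces[v]:
            out.update(F[fi])
        out.discard(v)
        return out

    remaining = n_faces
    while remaining > target_faces and heap:
        cost, va_ver, vb_ver, a, b, x = heapq.heappop(heap)
        if not (alive[a] and alive[b]):
            continue
        if version[a] != va_ver or version[b] != vb_ver:
            continue
        shared = vertex_faces[a] & vertex_faces[b]
        if not shared:
            continue  # stale edge
        # link condition: common neighbours must all come from shared faces
        common = neighbors(a) & neighbors(b)
        if len(common) != len(shared):
            continue
        # normal-flip guard
        moved = (vertex_faces[a] | vertex_faces[b]) - shared
        flip = False
        for fi in moved:
            f = F[fi].copy()
            p_old = V[f]
            n_old = np.cross(p_old[1] - p_old[0], p_old[2] - p_old[0])
            f_new = np.where(f == b, a, f)
            p_new = np.where((f == b)[:, None], x, V[f])
            n_new = np.cross(p_new[1] - p_new[0], p_new[2] - p_new[0])
            if len(set(f_new)) < 3 or n_old @ n_new <= 0:
                flip = True
                break
        if flip:
            continue

        # collapse b -> a at position x
        V[a] = x
        Q[a] = Q[a] + Q[b]
        alive[b] = False
        for fi in shared:
            face_alive[fi] = False
            for c in F[fi]:
                vertex_faces[c].discard(fi)
            remaining -= 1
        for fi in list(vertex_faces[b]):
            F[fi] = np.where(F[fi] == b, a, F[fi])
            vertex_faces[a].add(fi)
        vertex_faces[b] = set()
        version[a] += 1
        for nb in neighbors(a):
            push_edge(a, int(nb))

    new_faces = F[face_alive]
    used = np.unique(new_faces)
    remap = np.full(len(V), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return V[used], remap[new_faces]
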