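"""Mesh quality and comparison metrics.

Scaled Jacobian for 8-node hexahedra, dihedral feature angles,
predicted-vs-reference surface deviation with the normal-deviation
inclusion criterion ("nodal coverage"), Dice overlap of label masks, and
min-max-normalized RMS series differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MeshProximity, face_normals, vertex_normals_area_weighted

# hex corner ordering: bottom quad counter-clockwise (0-3), then top
# quad (4-7) directly above. Corner Jacobian edge triples are ordered so
# a unit cube yields +1 at every corner.
_BOTTOM = [(0, 1, 3, 4), (1, 2, 0, 5), (2, 3, 1, 6), (3, 0, 2, 7)]
_TOP = [(4, 7, 5, 0), (5, 4, 6, 1), (6, 5, 7, 2), (7, 6, 4, 3)]


def scaled_jacobian(hex_nodes: np.ndarray) -> np.ndarray:
    """Minimum normalized corner Jacobian of 8-node hexahedra, in [-1, 1].

    ``hex_nodes``: (..., 8, 3) corner coordinates. For each of the 8
    corners the three emanating edge vectors are unit-normalized and
    their determinant taken; the element value is the corner minimum.
    1 is a perfect cube; values <= 0 indicate degenerate/inverted
    elements.
    """
    x = np.asarray(hex_nodes, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    dets = np.empty(x.shape[:-2] + (8,))
    for ci, (k, a, b, c) in enumerate(_BOTTOM + _TOP):
        e1 = x[..., a, :] - x[..., k, :]
        e2 = x[..., b, :] - x[..., k, :]
        e3 = x[..., c, :] - x[..., k, :]
        m = np.stack([e1, e2, e3], axis=-2)
        norms = np.linalg.norm(m, axis=-1, keepdims=True)
        m = m / np.maximum(norms, 1e-300)
        dets[..., ci] = np.linalg.det(m)
    sj = dets.min(axis=-1)
    return sj[0] if single else sj


def _poly_normals(vertices, faces):
    """Unit normals for tri or quad faces (Newell for quads)."""
    faces = np.asarray(faces)
    if faces.shape[1] == 3:
        return face_normals(vertices, faces)
    p = vertices[faces]  # (F,4,3)
    n = np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 1])
    return n / np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-300)


def feature_angle(vertices: np.ndarray, faces: np.ndarray, edge) -> float:
    """Fold angle (degrees) between the two faces sharing ``edge``.

    0 deg = coplanar faces, 90 deg = perpendicular. Raises when the edge
    is not shared by exactly two faces.
    """
    a, b = int(edge[0]), int(edge[1])
    faces = np.asarray(faces)
    has = (faces == a).any(axis=1) & (faces == b).any(axis=1)
    idx = np.nonzero(has)[0]
    if len(idx) != 2:
        raise ValueError(
            f"edge ({a},{b}) is shared by {len(idx)} faces, need exactly 2"
        )
    n = _poly_normals(vertices, faces[idx])
    cosang = np.clip(n[0] @ n[1], -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def feature_angles_along_edges(vertices, faces, edges) -> np.ndarray:
    """Vectorized :func:`feature_angle` for many (2,)-edges; NaN when an
    edge is not interior (not shared by exactly two faces)."""
    faces = np.asarray(faces)
    k = faces.shape[1]
    # face-edge table
    pairs = np.concatenate(
        [faces[:, [i, (i + 1) % k]] for i in range(k)], axis=0
    )
    owner = np.tile(np.arange(len(faces)), k)
    key = np.sort(pairs, axis=1)
    order = np.lexsort((key[:, 1], key[:, 0]))
    key, owner = key[order], owner[order]
    normals = _poly_normals(vertices, faces)
    out = np.full(len(edges), np.nan)
    # map each query edge to its owners
    from collections import defaultdict

    table = defaultdict(list)
    for (u, v), o in zip(map(tuple, key), owner):
        table[(u, v)].append(o)
    for i, e in enumerate(edges):
        owners = table.get(tuple(sorted(map(int, e))), [])
        if len(owners) == 2:
            c = np.clip(normals[owners[0]] @ normals[owners[1]], -1, 1)
            out[i] = np.degrees(np.arccos(c))
    return out


@dataclass
class DeviationReport:
    """Per-node surface deviation with nodal-coverage accounting."""

    distances: np.ndarray          # mm, one per predicted node
    included: np.ndarray           # bool, normal-deviation criterion
    coverage: float                # percent of nodes included
    summary: dict                  # median/quartiles/max over included nodes
    kde: tuple | None              # (grid, density) Gaussian KDE, or None

    def __post_init__(self):
        assert 0.0 <= self.coverage <= 100.0


def surface_deviation(
    predicted, reference, max_normal_dev_deg: float = 20.0
) -> DeviationReport:
    """Distance from each predicted-mesh node to the reference surface.

    The ray from a node to its nearest reference point is compared with
    the node normal (area-weighted average of incident face normals,
    measured against the undirected normal line); nodes whose ray
    deviates by more than the cutoff are excluded from the statistics,
    and the retained fraction is reported as percent nodal coverage.
    """
    pv = predicted.vertices.view(np.ndarray)
    pf = predicted.faces.view(np.ndarray)
    rv = reference.vertices.view(np.ndarray)
    rf = reference.faces.view(np.ndarray)
    prox = MeshProximity(rv, rf)
    cp, dist, _ = prox.query(pv)
    normals = vertex_normals_area_weighted(pv, pf)
    ray = cp - pv
    with np.errstate(invalid="ignore"):
        ray_unit = ray / np.maximum(np.linalg.norm(ray, axis=1, keepdims=True), 1e-300)
    cosang = np.abs(np.einsum("ij,ij->i", ray_unit, normals))
    angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    included = (angle <= max_normal_dev_deg) | (dist < 1e-9)
    coverage = 100.0 * included.mean() if len(included) else 0.0

    d_in = dist[included]
    if len(d_in):
        summary = {
            "median": float(np.median(d_in)),
            "q25": float(np.percentile(d_in, 25)),
            "q75": float(np.percentile(d_in, 75)),
            "max": float(d_in.max()),
            "n": int(len(d_in)),
        }
    else:
        summary = {"median": np.nan, "q25": np.nan, "q75": np.nan, "max": np.nan, "n": 0}

    kde = None
    if len(d_in) > 2 and np.std(d_in) > 1e-12:
        from scipy.stats import gaussian_kde

        k = gaussian_kde(d_in)  # Scott bandwidth
        lo = max(0.0, d_in.min() - 4 * k.factor * d_in.std())
        hi = d_in.max() + 4 * k.factor * d_in.std()
        grid = np.linspace(lo, hi, 512)
        kde = (grid, k(grid))
    return DeviationReport(dist, included, float(coverage), summary, kde)


def dice(volume_a, volume_b, code) -> float:
    """Dice similarity coefficient 2|A^B| / (|A|+|B|) of one label code."""
    a = volume_a.mask(code) if hasattr(volume_a, "mask") else np.asarray(volume_a, bool)
    b = volume_b.mask(code) if hasattr(volume_b, "mask") else np.asarray(volume_b, bool)
    if a.shape != b.shape:
        raise ValueError(f"grid shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("both masks are empty")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def minmax_rms(series_a, series_b) -> tuple[float, float]:
    """RMS difference and its percentage of the reference min-max range.

    ``series_a`` is the reference series defining the normalization
    range.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series lengths differ")
    rms = float(np.sqrt(np.mean((a - b) ** 2)))
    rng = float(a.max() - a.min())
    if rng == 0:
        raise ValueError("reference series has zero min-max range")
    return rms, 100.0 * rms / rng
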