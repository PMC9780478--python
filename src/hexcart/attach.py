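"""Template-to-subject registration and attachment-site mapping.

Subject femoral surfaces are registered to a template femur with
iterative closest points (similarity transform by default, since
template and subjects differ in scale); the same transform then carries
every other tissue. Template attachment sites and joint-axis landmarks
are mapped by nearest-neighbour search in the template frame and
returned in the subject frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import HexcartError
from .geometry import MeshProximity


@dataclass
class SimilarityTransform:
    """x -> scale * rotation @ x + translation."""

    rotation: np.ndarray   # (3,3), det +1
    translation: np.ndarray
    scale: float = 1.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (np.atleast_2d(points) @ self.rotation.T) + self.translation

    def inverse(self) -> "SimilarityTransform":
        R_inv = self.rotation.T
        s_inv = 1.0 / self.scale
        return SimilarityTransform(R_inv, -s_inv * (R_inv @ self.translation), s_inv)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self after other: x -> self(other(x))."""
        return SimilarityTransform(
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation + self.translation,
            self.scale * other.scale,
        )


def _umeyama(src: np.ndarray, dst: np.ndarray, with_scale: bool) -> SimilarityTransform:
    """Least-squares similarity transform mapping src onto dst."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    xs = src - mu_s
    xd = dst - mu_d
    cov = xd.T @ xs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1
    R = U @ S @ Vt
    if with_scale:
        var_s = (xs**2).sum() / len(src)
        s = float(np.trace(np.diag(D) @ S) / var_s)
    else:
        s = 1.0
    t = mu_d - s * R @ mu_s
    return SimilarityTransform(R, t, s)


def _principal_prealign(moving: np.ndarray, target: np.ndarray) -> SimilarityTransform:
    """Centroid + principal-axes pre-alignment, sign ambiguity resolved
    by trying the four proper axis-flip combinations and keeping the one
    with the lowest nearest-point residual."""
    cm = moving.mean(axis=0)
    ct = target.mean(axis=0)
    _, _, vm = np.linalg.svd(moving - cm, full_matrices=False)
    _, _, vt = np.linalg.svd(target - ct, full_matrices=False)
    # make both frames proper rotations so every flip combo has det +1
    if np.linalg.det(vm) < 0:
        vm = vm * np.array([[1.0], [1.0], [-1.0]])
    if np.linalg.det(vt) < 0:
        vt = vt * np.array([[1.0], [1.0], [-1.0]])
    tree = cKDTree(target)
    best = None
    for fx in (1, -1):
        for fy in (1, -1):
            F = np.diag([fx, fy, fx * fy])  # proper rotations only
            R = vt.T @ F @ vm
            if np.linalg.det(R) < 0:
                continue
            t = ct - R @ cm
            trans = SimilarityTransform(R, t, 1.0)
            d, _ = tree.query(trans.apply(moving[:: max(1, len(moving) // 500)]))
            res = float(np.mean(d**2))
            if best is None or res < best[0]:
                best = (res, trans)
    return best[1]


def register_icp(
    moving_femur,
    template_femur,
    with_scale: bool = True,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> SimilarityTransform:
    """ICP registration of a subject femur onto the template femur.

    Correspondences are point-to-nearest-surface-point on the template
    (robust to differing tessellations). Returns the transform taking
    subject coordinates into the template frame; convergence is declared
    when the RMS residual change drops below ``tol``, else the transform
    at ``max_iter`` is returned.
    """
    mv = moving_femur.vertices.view(np.ndarray)
    tv = template_femur.vertices.view(np.ndarray)
    tf = template_femur.faces.view(np.ndarray)
    if len(mv) < 4 or len(tv) < 4:
        raise HexcartError("registration requires non-degenerate surfaces")
    prox = MeshProximity(tv, tf)
    transform = _principal_prealign(mv, tv)
    prev_res = np.inf
    for _ in range(max_iter):
        cur = transform.apply(mv)
        closest, d, _ = prox.query(cur)
        res = float(np.sqrt(np.mean(d**2)))
        if not np.isfinite(res):
            raise HexcartError("ICP diverged (non-finite residual)")
        if abs(prev_res - res) < tol:
            break
        prev_res = res
        transform = _umeyama(mv, closest, with_scale)
    return transform


def map_attachment_sites(
    transform: SimilarityTransform,
    atlas,
    subject_surfaces: dict,
) -> list[dict]:
    """Map template sites and joint-axis landmarks onto subject meshes.

    ``transform`` maps subject -> template frame. Each template site is
    matched to the nearest subject node in the template frame (ties
    broken by lowest node id); the returned coordinates are the matched
    node's original subject-frame position. Axis landmarks map the same
    way against the femur.
    """
    if not subject_surfaces:
        raise HexcartError("no subject surfaces supplied")
    trees = {}
    verts = {}
    for tissue, mesh in subject_surfaces.items():
        v = mesh.vertices.view(np.ndarray)
        if len(v) == 0:
            raise HexcartError(f"subject surface {tissue!r} is empty")
        verts[tissue] = v
        trees[tissue] = cKDTree(transform.apply(v))

    default_tissue = "femur" if "femur" in trees else next(iter(trees))
    records = []
    entries = [(name, tissue, np.asarray(xyz)) for name, tissue, xyz in atlas.sites]
    entries += [
        (f"axis_{k}", default_tissue, np.asarray(p))
        for k, p in enumerate(atlas.joint_axis_points)
    ]
    for name, tissue, xyz in entries:
        tissue = tissue if tissue in trees else default_tissue
        d, idx = trees[tissue].query(xyz, k=1)
        # deterministic tie-break: lowest node id among equal distances
        dd, ii = trees[tissue].query(xyz, k=min(4, len(verts[tissue])))
        ties = np.atleast_1d(ii)[np.isclose(np.atleast_1d(dd), d)]
        idx = int(ties.min())
        records.append(
            {
                "name": str(name),
                "tissue": tissue,
                "node_id": idx,
                "xyz": [float(c) for c in verts[tissue][idx]],
            }
        )
    return records
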