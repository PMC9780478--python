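"""Label-mask -> surface reconstruction chain."""

import numpy as np
import pytest
import trimesh
from scipy.ndimage import binary_dilation, binary_erosion

from hexcart import reconstruct as rc
from hexcart.geometry import MeshProximity, signed_volume
from hexcart.volume import LabelVolume


def _volume_from_mask(mask, code=4, name="cartilage", spacing=1.0):
    return LabelVolume(
        mask.astype(np.int16) * code, [spacing] * 3, [0, 0, 0], {code: name}
    )


# ---------------------------------------------------------------------------
# close_labels
# ---------------------------------------------------------------------------


def test_closing_idempotent_on_convex_solid():
    mask = np.zeros((16, 16, 16), bool)
    mask[3:13, 3:13, 3:13] = True
    lv = _volume_from_mask(mask)
    out = rc.close_labels(lv, "cartilage")
    assert np.array_equal(out.codes, lv.codes)


def test_closing_fills_interior_void():
    mask = np.zeros((16, 16, 16), bool)
    mask[3:13, 3:13, 3:13] = True
    mask[8, 8, 8] = False
    out = rc.close_labels(_volume_from_mask(mask), "cartilage")
    assert out.codes[8, 8, 8] == 4


def test_closing_seals_slit_against_dilate_erode_oracle():
    """2-voxel slit: closing with the 5-voxel kernel equals brute-force
    dilation-then-erosion with the same cube."""
    mask = np.zeros((24, 24, 12), bool)
    mask[2:22, 2:22, 2:10] = True
    mask[11:13, 2:22, 2:10] = False  # 2-voxel-wide slit
    out = rc.close_labels(_volume_from_mask(mask), "cartilage")
    k = np.ones((5, 5, 5), bool)
    pad = 5
    padded = np.pad(mask, pad)
    oracle = binary_erosion(binary_dilation(padded, k), k)[pad:-pad, pad:-pad, pad:-pad]
    assert np.array_equal(out.codes == 4, oracle)
    assert (out.codes[11:13, 5:19, 5] == 4).all()  # slit actually sealed


def test_closing_kernel_widths_differ_by_class():
    # a 4-voxel slit closes under the 5-kernel but not the 3-kernel
    mask = np.zeros((24, 24, 12), bool)
    mask[2:22, 2:22, 2:10] = True
    mask[10:14, 2:22, 2:10] = False
    cart = rc.close_labels(_volume_from_mask(mask), "cartilage")
    bone = rc.close_labels(_volume_from_mask(mask), "bone")
    assert (cart.codes[10:14, 10, 5] == 4).all()
    assert (bone.codes[10:14, 10, 5] == 0).all()


def test_closing_empty_mask_errors():
    lv = _volume_from_mask(np.zeros((8, 8, 8), bool))
    with pytest.raises(ValueError, match="cartilage"):
        rc.close_labels(lv, "cartilage", code=4)


# ---------------------------------------------------------------------------
# extract_surface
# ---------------------------------------------------------------------------


def test_extract_cube_closed_euler_two():
    mask = np.zeros((14, 14, 14), bool)
    mask[2:12, 2:12, 2:12] = True
    surf = rc.extract_surface(_volume_from_mask(mask), 4)
    assert surf.is_watertight
    assert surf.euler_number == 2


def test_extract_sphere_area_within_5pct():
    ii, jj, kk = np.meshgrid(*(np.arange(24),) * 3, indexing="ij")
    c = 11.5
    mask = ((ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2) <= 64
    surf = rc.extract_surface(_volume_from_mask(mask), 4)
    assert surf.area == pytest.approx(4 * np.pi * 64, rel=0.05)


def test_extract_mask_touching_boundary_still_closed():
    mask = np.ones((10, 10, 6), bool)  # fills the whole grid
    surf = rc.extract_surface(_volume_from_mask(mask), 4)
    assert surf.is_watertight
    assert signed_volume(surf.vertices.view(np.ndarray), surf.faces.view(np.ndarray)) > 0


def test_extract_absent_code_errors():
    with pytest.raises(ValueError, match="absent"):
        rc.extract_surface(_volume_from_mask(np.ones((6, 6, 6), bool)), 9)


# ---------------------------------------------------------------------------
# keep_largest_component
# ---------------------------------------------------------------------------


def _sphere(radius, center):
    s = trimesh.creation.icosphere(subdivisions=2, radius=radius)
    s.apply_translation(center)
    return s


def test_keep_largest_of_two_spheres():
    merged = trimesh.util.concatenate([_sphere(8, (0, 0, 0)), _sphere(4, (30, 0, 0))])
    out = rc.keep_largest_component(merged)
    assert len(out.split(only_watertight=False)) == 1
    assert out.volume == pytest.approx(_sphere(8, (0, 0, 0)).volume, rel=1e-6)


def test_keep_largest_single_component_identity():
    s = _sphere(5, (0, 0, 0))
    out = rc.keep_largest_component(s)
    assert len(out.faces) == len(s.faces)


def test_keep_largest_of_three_matches_volume_oracle():
    parts = [_sphere(3, (0, 0, 0)), _sphere(6, (30, 0, 0)), _sphere(4.5, (-30, 0, 0))]
    merged = trimesh.util.concatenate(parts)
    out = rc.keep_largest_component(merged)
    vols = [
        abs(signed_volume(p.vertices.view(np.ndarray), p.faces.view(np.ndarray)))
        for p in parts
    ]
    got = abs(signed_volume(out.vertices.view(np.ndarray), out.faces.view(np.ndarray)))
    assert got == pytest.approx(max(vols), rel=1e-9)


# ---------------------------------------------------------------------------
# simplify_smooth
# ---------------------------------------------------------------------------


def test_decimation_hits_80pct_reduction():
    s = trimesh.creation.icosphere(subdivisions=4, radius=20.0)  # 5120 faces
    out = rc.simplify_smooth(s, 0.8, 0)
    assert len(out.faces) == pytest.approx(0.2 * len(s.faces), rel=0.02)
    assert out.is_watertight
    r = np.linalg.norm(out.vertices, axis=1)
    assert np.abs(r - 20).max() < 0.5


def test_simplify_identity_when_disabled():
    s = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
    out = rc.simplify_smooth(s, 0.0, 0)
    assert np.allclose(out.vertices, s.vertices)
    assert np.array_equal(out.faces, s.faces)


def test_laplacian_shrinkage_monotone():
    s = trimesh.creation.icosphere(subdivisions=3, radius=20.0)
    radii = []
    for iters in (0, 3, 9, 15):
        out = rc.simplify_smooth(s, 0.0, iters)
        radii.append(np.linalg.norm(out.vertices, axis=1).mean())
    assert all(a > b for a, b in zip(radii, radii[1:]))


def test_simplify_requires_enough_triangles():
    tiny = trimesh.creation.box()
    with pytest.raises(ValueError, match="100"):
        rc.simplify_smooth(tiny, 0.5, 1)


# ---------------------------------------------------------------------------
# repair_surface
# ---------------------------------------------------------------------------


def test_repair_flipped_triangles_signed_volume_positive():
    box = trimesh.creation.box(extents=(5, 5, 5))
    f = box.faces.copy()
    f[:3] = f[:3, ::-1]
    broken = trimesh.Trimesh(box.vertices.copy(), f, process=False)
    fixed = rc.repair_surface(broken, "bone_full")
    assert fixed.is_watertight
    v = signed_volume(fixed.vertices.view(np.ndarray), fixed.faces.view(np.ndarray))
    assert v == pytest.approx(125.0)


def test_repair_identity_on_clean_surface():
    s = trimesh.creation.icosphere(subdivisions=2, radius=4.0)
    out = rc.repair_surface(s, "bone_full")
    assert out.volume == pytest.approx(s.volume, rel=1e-9)


def test_cartilage_repair_preserves_hole_boundaries(slab_with_hole):
    """Normals-only repair never touches topology: boundary edge count of
    a holed surface is unchanged."""
    surf = slab_with_hole.surfaces["cartilage"]
    # punch the mesh open by deleting faces near the hole wall to create
    # a true open boundary
    V = surf.vertices.view(np.ndarray)
    keep = np.linalg.norm(V[surf.faces.view(np.ndarray)].mean(axis=1)[:, :2], axis=1) > 2.5
    opened = trimesh.Trimesh(V.copy(), surf.faces.view(np.ndarray)[keep], process=False)

    def boundary_edge_count(m):
        e = np.sort(m.edges.reshape(-1, 2), axis=1)
        _, c = np.unique(e, axis=0, return_counts=True)
        return int((c == 1).sum())

    before = boundary_edge_count(opened)
    out = rc.repair_surface(opened, "cartilage_normals_only")
    assert boundary_edge_count(out) == before
    assert len(out.faces) == len(opened.faces)


def test_repair_unknown_mode():
    with pytest.raises(ValueError):
        rc.repair_surface(trimesh.creation.box(), "frobnicate")


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


def test_full_chain_hausdorff_to_ground_truth(slab):
    """close -> extract -> largest -> simplify/smooth -> repair lands
    within two voxel diagonals of the analytic phantom surface."""
    surf = rc.reconstruct_tissue(slab.label_volume, "cartilage")
    truth = slab.surfaces["cartilage"]
    d1 = MeshProximity(
        truth.vertices.view(np.ndarray), truth.faces.view(np.ndarray)
    ).query(surf.vertices.view(np.ndarray))[1]
    d2 = MeshProximity(
        surf.vertices.view(np.ndarray), surf.faces.view(np.ndarray)
    ).query(truth.vertices.view(np.ndarray))[1]
    assert max(d1.max(), d2.max()) < 2 * slab.label_volume.voxel_diagonal
    assert signed_volume(surf.vertices.view(np.ndarray), surf.faces.view(np.ndarray)) > 0
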