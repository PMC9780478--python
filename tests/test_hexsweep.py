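"""Swept-extrusion hex meshing: grids, degenerate taxonomy, repair,
optimization, subdivision and the fallback cascade."""

import numpy as np
import pytest

import hexcart as hc
from hexcart import hexsweep as hs
from hexcart.errors import (
    DegenerateClassificationError,
    QualityError,
    StrategyFailure,
)
from hexcart.metrics import scaled_jacobian


# ---------------------------------------------------------------------------
# synthetic grids for degenerate configurations
# ---------------------------------------------------------------------------


def grid_from_mask(valid: np.ndarray) -> hs.SweepGrid:
    """SweepGrid over a flat synthetic slab from a node validity mask."""
    valid = np.asarray(valid, dtype=bool)
    m, n = valid.shape
    ii, jj = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    bone = np.stack([2.0 * ii, 2.0 * jj, np.zeros_like(ii, float)], axis=-1)
    joint = bone + [0, 0, 2.0]
    origins = bone + [0, 0, 10.0]
    directions = np.broadcast_to([0.0, 0.0, -1.0], origins.shape).copy()
    return hs.SweepGrid(origins, directions, bone, joint, valid.copy(),
                        "tibial", "synthetic", 2.0)


def classify_mask(valid):
    sheet = hs.build_hex_sheet(grid_from_mask(valid))
    return sheet, hs.classify_degenerates(sheet)


def test_full_grid_element_and_node_counts():
    sheet = hs.build_hex_sheet(grid_from_mask(np.ones((5, 4), bool)))
    assert len(sheet.hexes) == 4 * 3
    assert len(sheet.nodes) == 2 * 20
    assert sheet.scaled_jacobians().min() == pytest.approx(1.0)


def test_notch_produces_six_node_element():
    valid = np.ones((4, 4), bool)
    valid[0, 0] = False  # concave notch
    sheet = hs.build_hex_sheet(grid_from_mask(valid))
    assert len(sheet.wedges) == 1
    e = sheet.hexes[sheet.wedges[0].elem]
    assert len(set(e.tolist())) == 6


def test_classify_clean_sheet_empty(slab_sheet):
    assert hs.classify_degenerates(slab_sheet) == []


def test_classify_corner():
    valid = np.ones((4, 4), bool)
    valid[0, 0] = False
    _, recs = classify_mask(valid)
    assert [r.klass for r in recs] == ["corner"]


def test_classify_peak():
    valid = np.ones((2, 3), bool)
    valid[1, 2] = False  # protruding tip next to a single full cell
    _, recs = classify_mask(valid)
    assert [r.klass for r in recs] == ["peak"]


def test_classify_step_aligned_collapse():
    """Two wedges whose missing corners collapse onto one shared apex."""
    valid = np.zeros((2, 3), bool)
    valid[0, :] = True
    valid[1, 1] = True
    _, recs = classify_mask(valid)
    assert len(recs) == 1
    assert recs[0].klass == "step"
    assert len(recs[0].element_ids) == 2
    assert recs[0].shared_topological_indices != ()


def test_classify_mirror_shared_missing_node():
    valid = np.ones((3, 2), bool)
    valid[1, 1] = False  # both cells miss the same shared node
    _, recs = classify_mask(valid)
    assert len(recs) == 1
    assert recs[0].klass == "mirror"
    assert len(recs[0].element_ids) == 2


def test_classify_stair_three_chain():
    valid = np.ones((3, 3), bool)
    valid[0, 0] = valid[0, 2] = valid[2, 2] = False
    _, recs = classify_mask(valid)
    assert [r.klass for r in recs] == ["stair"]
    assert len(recs[0].element_ids) == 3


def test_classify_unclassifiable_raises_with_ids():
    valid = np.ones((3, 3), bool)
    valid[0, 0] = valid[2, 0] = valid[0, 2] = valid[2, 2] = False
    sheet = hs.build_hex_sheet(grid_from_mask(valid))
    with pytest.raises(DegenerateClassificationError) as err:
        hs.classify_degenerates(sheet)
    assert len(err.value.element_ids) == 4


# ---------------------------------------------------------------------------
# repair
# ---------------------------------------------------------------------------


def _assert_all_eight_distinct(sheet):
    for e in sheet.hexes:
        assert len(set(e.tolist())) == 8


def test_repair_clean_sheet_identity(slab_sheet):
    out = hs.repair_degenerates(slab_sheet, [])
    assert np.allclose(out.nodes, slab_sheet.nodes)
    assert np.array_equal(out.hexes, slab_sheet.hexes)


def test_repair_peak_deletes_one_element():
    valid = np.ones((2, 3), bool)
    valid[1, 2] = False
    sheet, recs = classify_mask(valid)
    assert recs[0].klass == "peak"
    out = hs.repair_degenerates(sheet, recs)
    assert len(out.hexes) == len(sheet.hexes) - 1
    _assert_all_eight_distinct(out)


def test_repair_corner_creates_nodes_keeps_elements():
    valid = np.ones((4, 4), bool)
    valid[0, 0] = False
    sheet, recs = classify_mask(valid)
    out = hs.repair_degenerates(sheet, recs)
    assert len(out.hexes) == len(sheet.hexes)
    assert len(out.nodes) == len(sheet.nodes) + 2  # reconstructed pair
    _assert_all_eight_distinct(out)
    # extrapolated corner lands on the regular lattice
    assert out.scaled_jacobians().min() > 0.9


def test_repair_step_and_stair_delete_groups():
    valid = np.ones((3, 3), bool)
    valid[2, 0] = valid[2, 2] = False  # staircase ending against full rows
    sheet, recs = classify_mask(valid)
    assert [r.klass for r in recs] == ["step"]
    out = hs.repair_degenerates(sheet, recs)
    assert len(out.hexes) == len(sheet.hexes) - 2  # step removes the pair
    valid = np.ones((3, 3), bool)
    valid[0, 0] = valid[0, 2] = valid[2, 2] = False
    sheet, recs = classify_mask(valid)
    out = hs.repair_degenerates(sheet, recs)
    assert len(out.hexes) == len(sheet.hexes) - 3  # stair removes the triple
    _assert_all_eight_distinct(out)


def test_repair_idempotent():
    valid = np.ones((4, 4), bool)
    valid[0, 0] = False
    sheet, recs = classify_mask(valid)
    once = hs.repair_degenerates(sheet, recs)
    twice = hs.repair_degenerates(once, hs.classify_degenerates(once))
    assert np.allclose(once.nodes, twice.nodes)
    assert np.array_equal(once.hexes, twice.hexes)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


def test_optimize_compliant_sheet_unchanged(slab_sheet):
    out = hs.optimize_quality(slab_sheet, 0.5, max_iterations=50)
    assert np.allclose(out.nodes, slab_sheet.nodes)


def test_optimize_recovers_inverted_node(slab, slab_sheet):
    sheet = slab_sheet.copy()
    # push one interior bone node past its joint partner: inverted element
    rim = set(int(v) for v in sheet.boundary_nodes())
    interior = [v for v in np.nonzero(sheet.is_bone)[0] if int(v) not in rim]
    v = interior[len(interior) // 2]
    sheet.nodes[v] = sheet.nodes[sheet.partner[v]] + [0, 0, 0.5]
    assert sheet.scaled_jacobians().min() < 0
    out = hs.optimize_quality(sheet, 0.0, surface=slab.surfaces["cartilage"])
    assert out.scaled_jacobians().min() >= 0


def test_optimize_guard_terminates_with_error(condyle_stage2):
    """An unreachable target raises instead of looping forever."""
    with pytest.raises(QualityError) as err:
        hs.optimize_quality(condyle_stage2, 0.99999, max_iterations=4)
    assert err.value.worst  # reports the worst elements


# ---------------------------------------------------------------------------
# subdivision
# ---------------------------------------------------------------------------


def _face_audit(hexes):
    faces = hs.hex_faces(hexes).reshape(-1, 4)
    key = np.sort(faces, axis=1)
    _, counts = np.unique(key, axis=0, return_counts=True)
    return counts


def test_subdivide_inplane_counts_and_corners(slab_sheet):
    out = hs.subdivide_inplane(slab_sheet)
    assert len(out.hexes) == 4 * len(slab_sheet.hexes)
    # original corner nodes preserved bitwise
    assert np.allclose(out.nodes[: len(slab_sheet.nodes)], slab_sheet.nodes)
    assert _face_audit(out.hexes).max() <= 2  # conforming


def test_subdivide_depth_layers_and_counts(slab_sheet):
    mesh = hs.subdivide_depth(slab_sheet, 4)
    assert len(mesh.hexes) == 4 * len(slab_sheet.hexes)
    n_pairs = int(slab_sheet.is_bone.sum())
    assert len(mesh.nodes) == n_pairs * 5
    assert mesh.is_conforming()
    # equal layer thickness t/4 on the uniform slab
    corners = mesh.nodes[mesh.hexes]
    depth_edges = np.linalg.norm(corners[:, 4] - corners[:, 0], axis=1)
    assert np.allclose(depth_edges, 0.75, atol=0.05)


def test_subdivide_depth_single_layer_identity(slab_sheet):
    mesh = hs.subdivide_depth(slab_sheet, 1)
    assert len(mesh.hexes) == len(slab_sheet.hexes)
    assert len(mesh.nodes) == len(slab_sheet.nodes)
    assert sorted(map(tuple, np.sort(mesh.nodes, axis=0).round(9).tolist())) == sorted(
        map(tuple, np.sort(slab_sheet.nodes, axis=0).round(9).tolist())
    )


# ---------------------------------------------------------------------------
# sweep grids on phantoms
# ---------------------------------------------------------------------------


def test_rectilinear_grid_pitch_and_mask(slab):
    cart = slab.surfaces["cartilage"]
    grid = hs.make_sweep_grid(cart, "tibial", strategy="rectilinear")
    gi, gj = np.nonzero(grid.valid)
    hits = grid.bone_hits[gi, gj]
    # hit spacing equals the grid pitch along each footprint axis
    xs = np.unique(hits[:, 0].round(6))
    assert np.allclose(np.diff(xs), grid.pitch, atol=0.05)


def test_grid_mask_false_over_hole(slab_with_hole):
    cart = slab_with_hole.surfaces["cartilage"]
    grid = hs.make_sweep_grid(cart, "tibial", strategy="rectilinear")
    m, n = grid.shape
    uv = grid.origins[..., :2]
    r = np.hypot(uv[..., 0], uv[..., 1])
    inside_fp = (np.abs(uv[..., 0]) < 8) & (np.abs(uv[..., 1]) < 4)
    assert not grid.valid[r < 1.5].any()           # hole core rays miss
    assert grid.valid[(r > 3.0) & inside_fp].all()  # interior rays hit


def test_femoral_grid_paired_hits(condyle):
    grid = hs.make_sweep_grid(condyle.surfaces["femoral_cartilage"], "femoral")
    v = grid.valid
    assert np.isfinite(grid.bone_hits[v]).all()
    assert np.isfinite(grid.joint_hits[v]).all()
    # bone-side hits are radially inside their joint-side mates
    b = np.linalg.norm(grid.bone_hits[v][:, [0, 2]], axis=1)
    j = np.linalg.norm(grid.joint_hits[v][:, [0, 2]], axis=1)
    assert (j > b).all()


def test_sweep_failure_signal():
    """A surface too small for the pitch raises a strategy failure."""
    tiny = hc.make_slab_phantom(6, 3, 1.5, voxel_spacing_mm=0.5)
    with pytest.raises((StrategyFailure, hs.MeshingError)):
        hs.make_sweep_grid(
            tiny.surfaces["cartilage"], "tibial", target_edge_mm=4.0,
            strategy="rectilinear",
        )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def test_mesh_cartilage_slab_contract(slab):
    params = hc.MeshParams()
    mesh = hs.mesh_cartilage(
        slab.surfaces["cartilage"], "tibial", slab.surfaces["bone"], params=params
    )
    assert mesh.provenance["fallbacks"] == []
    assert mesh.layer_count == 4
    assert mesh.is_conforming()
    # boundary skin is a closed 2-manifold (watertight)
    import trimesh

    skin = mesh.boundary_quads()
    tris = np.concatenate([skin[:, [0, 1, 2]], skin[:, [0, 2, 3]]])
    assert trimesh.Trimesh(mesh.nodes, tris, process=False).is_watertight
    # no duplicate nodes within 1e-6 mm
    from scipy.spatial import cKDTree

    pairs = cKDTree(mesh.nodes).query_pairs(1e-6)
    assert not pairs


def test_mesh_cartilage_fallback_cascade(tibial_phantom, monkeypatch):
    """When the sector grid fails, provenance records the simplified-grid
    fallback and the rectilinear strategy delivers the mesh."""
    orig = hs.make_sweep_grid

    def flaky(surface, site, strategy=None, **kw):
        if site == "tibial" and strategy in (None, "sectors"):
            raise StrategyFailure("forced sector-grid failure")
        return orig(surface, site, strategy=strategy, **kw)

    monkeypatch.setattr(hs, "make_sweep_grid", flaky)
    mesh = hs.mesh_cartilage(
        tibial_phantom.surfaces["tibial_cartilage_medial"],
        "tibial",
        tibial_phantom.surfaces["tibia"],
    )
    assert "tibial_simplified_grid" in mesh.provenance["fallbacks"]
    assert mesh.provenance["strategy"] == "rectilinear"


def test_condyle_stage2_quality(condyle_stage2):
    assert condyle_stage2.scaled_jacobians().min() >= 0.5


def test_condyle_final_mesh(condyle_mesh):
    assert condyle_mesh.is_conforming()
    assert condyle_mesh.provenance["sj_pre_blend_min"] >= 0.5
    assert condyle_mesh.provenance["sj_final_min"] > 0
    mean_edge = hs.inplane_edge_lengths(condyle_mesh).mean()
    assert mean_edge == pytest.approx(1.0, rel=0.25)


def test_scaled_jacobian_matches_brute_force_small_instance(slab_sheet):
    """Module SJ vs direct corner-determinant oracle on <=10 elements."""
    sub = slab_sheet.hexes[:8]
    corners = slab_sheet.nodes[sub]

    def brute(h):
        B = [(0, 1, 3, 4), (1, 2, 0, 5), (2, 3, 1, 6), (3, 0, 2, 7)]
        T = [(4, 7, 5, 0), (5, 4, 6, 1), (6, 5, 7, 2), (7, 6, 4, 3)]
        best = np.inf
        for k, a, b, c in B + T:
            m = np.array([h[a] - h[k], h[b] - h[k], h[c] - h[k]])
            m = m / np.linalg.norm(m, axis=1, keepdims=True)
            best = min(best, np.linalg.det(m))
        return best

    ours = scaled_jacobian(corners)
    for k in range(len(sub)):
        assert abs(ours[k] - brute(corners[k])) < 1e-10
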