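"""Phantom generators against their analytic ground truth."""

import numpy as np
import pytest
import trimesh

import hexcart as hc
from hexcart.geometry import (
    MeshProximity,
    ray_mesh_intersections,
    signed_volume,
)


def _z_extent_at(surface, x, y):
    """z-range of the surface hit along the vertical line through (x, y)."""
    V = surface.vertices.view(np.ndarray)
    F = surface.faces.view(np.ndarray)
    _, _, _, pts = ray_mesh_intersections(
        np.array([[x, y, 100.0]]), np.array([[0.0, 0.0, -1.0]]), V, F
    )
    return pts[:, 2].min(), pts[:, 2].max()


def test_slab_voxel_layers(slab):
    """A 3 mm slab at 0.5 mm spacing spans 6 voxel layers."""
    mask = slab.label_volume.mask("cartilage")
    i, j = mask.shape[0] // 2, mask.shape[1] // 2
    assert mask[i, j, :].sum() == 6


def test_slab_thickness_recoverable_by_ray_probe(slab):
    lo, hi = _z_extent_at(slab.surfaces["cartilage"], 0.0, 0.0)
    t = slab.ground_truth["thickness_mm"]
    assert hi - lo == pytest.approx(t, abs=slab.label_volume.voxel_diagonal)


def test_hole_voxel_count_matches_cylinder(slab, slab_with_hole):
    """Voxels removed by an r=2 hole ~ pi r^2 t / voxel volume."""
    full = slab.label_volume.mask("cartilage").sum()
    holed = slab_with_hole.label_volume.mask("cartilage").sum()
    vv = slab.label_volume.voxel_volume
    removed = (full - holed) * vv
    analytic = np.pi * 2.0**2 * 3.0
    assert removed == pytest.approx(analytic, rel=0.15)


def test_hole_outside_footprint_rejected():
    with pytest.raises(ValueError, match="outside"):
        hc.make_slab_phantom(20, 10, 3, hole_specs=[(30.0, 0.0, 2.0)])


def test_thickness_below_resolution_rejected():
    with pytest.raises(ValueError, match="resolvable"):
        hc.make_slab_phantom(20, 10, 0.8, voxel_spacing_mm=0.5)


def test_curved_slab_sagittal_drop(curved_slab):
    """Chord geometry: drop over L=20 chord on R=30 is R - sqrt(R^2-100)."""
    surf = curved_slab.surfaces["cartilage"]
    apex_lo, _ = _z_extent_at(surf, 0.0, 0.0)
    # bone-side height near the slab end (developed coordinate ~9.9 mm)
    R = 30.0
    x_end = R * np.sin(9.9 / R)
    end_lo, _ = _z_extent_at(surf, x_end, 0.0)
    s_end = 9.9
    expected_drop = R - np.sqrt(R**2 - (R * np.sin(s_end / R)) ** 2)
    drop = apex_lo - end_lo
    assert drop == pytest.approx(expected_drop, abs=2 * curved_slab.label_volume.voxel_diagonal)


def test_femoral_cartilage_offset_at_apex(condyle):
    """Joint-side surface sits thickness beyond the bone radius at apex."""
    cart = condyle.surfaces["femoral_cartilage"]
    V = cart.vertices.view(np.ndarray)
    F = cart.faces.view(np.ndarray)
    _, t, _, pts = ray_mesh_intersections(
        np.array([[0.0, 0.0, 0.0]]), np.array([[0.0, 0.0, 1.0]]), V, F
    )
    R = condyle.ground_truth["radius_mm"]
    T = condyle.ground_truth["thickness_mm"]
    vd = condyle.label_volume.voxel_diagonal
    assert t.min() == pytest.approx(R, abs=vd)
    assert t.max() == pytest.approx(R + T, abs=vd)


def test_tibial_two_compartments(tibial_phantom):
    lv = tibial_phantom.label_volume
    assert "tibial_cartilage_medial" in lv.tissue_map.values()
    assert "tibial_cartilage_lateral" in lv.tissue_map.values()
    for name in ("tibial_cartilage_medial", "tibial_cartilage_lateral"):
        surf = tibial_phantom.surfaces[name]
        assert surf.is_watertight
        assert len(surf.split(only_watertight=False)) == 1


def test_tibial_edge_hole_flagged():
    ph = hc.make_joint_phantom("tibial", hole_specs=[(-2.0, 0.0, 2.0)])
    assert ph.ground_truth["exercises_fallback_grid"]
    ph2 = hc.make_joint_phantom("tibial", hole_specs=[(-12.5, 0.0, 1.5)])
    assert not ph2.ground_truth["exercises_fallback_grid"]


def test_patellar_single_component(patellar_phantom):
    surf = patellar_phantom.surfaces["patellar_cartilage"]
    assert len(surf.split(only_watertight=False)) == 1


def test_all_phantom_surfaces_closed_and_outward(slab, condyle, tibial_phantom):
    for ph in (slab, condyle, tibial_phantom):
        for name, surf in ph.surfaces.items():
            assert surf.is_watertight, name
            v = surf.vertices.view(np.ndarray)
            f = surf.faces.view(np.ndarray)
            assert signed_volume(v, f) > 0, name


def test_atlas_sites(atlas160):
    names = [n for n, _, _ in atlas160.sites]
    assert len(names) == 160
    assert len(set(names)) == 160
    prox = MeshProximity(
        atlas160.femur_surface.vertices.view(np.ndarray),
        atlas160.femur_surface.faces.view(np.ndarray),
    )
    _, d, _ = prox.query(atlas160.site_array())
    assert d.max() < 1e-9
    assert len(atlas160.joint_axis_points) == 2


def test_atlas_sites_transform_exactly(atlas160):
    from hexcart.attach import SimilarityTransform
    from scipy.spatial.transform import Rotation

    R = Rotation.from_euler("xyz", [0.2, -0.4, 1.0]).as_matrix()
    tr = SimilarityTransform(R, np.array([5.0, -2.0, 3.0]), 1.25)
    pts = atlas160.site_array()
    assert np.allclose(tr.apply(pts), 1.25 * pts @ R.T + [5.0, -2.0, 3.0], atol=1e-12)


def test_atlas_requires_sites():
    with pytest.raises(ValueError):
        hc.make_template_atlas(0)


def test_voxelize_unit_cube():
    lv = hc.voxelize_surface(trimesh.creation.box(extents=(1, 1, 1)), 0.1)
    assert lv.mask(1).sum() * 0.1**3 == pytest.approx(1.0, rel=0.02)


def test_voxelize_sphere_volume():
    sph = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
    lv = hc.voxelize_surface(sph, 0.5)
    assert lv.mask(1).sum() * 0.5**3 == pytest.approx(4 / 3 * np.pi * 125, rel=0.05)


def test_voxelize_open_surface_rejected():
    box = trimesh.creation.box(extents=(1, 1, 1))
    open_surf = trimesh.Trimesh(box.vertices.copy(), box.faces[:-2].copy(), process=False)
    with pytest.raises(ValueError, match="closed"):
        hc.voxelize_surface(open_surf, 0.1)


def test_voxelize_extract_round_trip_hausdorff(slab):
    """Voxelize -> re-extract stays within one voxel diagonal of the
    original surface (sampled symmetric Hausdorff)."""
    from hexcart.reconstruct import extract_surface

    surf = slab.surfaces["cartilage"]
    lv = hc.voxelize_surface(surf, 0.5)
    back = extract_surface(lv, 1)
    d1 = MeshProximity(
        back.vertices.view(np.ndarray), back.faces.view(np.ndarray)
    ).query(surf.vertices.view(np.ndarray))[1]
    d2 = MeshProximity(
        surf.vertices.view(np.ndarray), surf.faces.view(np.ndarray)
    ).query(back.vertices.view(np.ndarray))[1]
    assert max(d1.max(), d2.max()) < lv.voxel_diagonal


def test_phantoms_deterministic():
    a = hc.make_joint_phantom("femoral", voxel_spacing_mm=1.0)
    b = hc.make_joint_phantom("femoral", voxel_spacing_mm=1.0)
    assert np.array_equal(a.label_volume.codes, b.label_volume.codes)
    assert np.allclose(
        a.surfaces["femoral_cartilage"].vertices,
        b.surfaces["femoral_cartilage"].vertices,
    )
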