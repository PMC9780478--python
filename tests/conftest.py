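"""Shared fixtures: phantoms and staged meshes are session-scoped since
several test modules probe the same geometry."""

import numpy as np
import pytest

import hexcart as hc
from hexcart import hexsweep as hs


@pytest.fixture(scope="session")
def slab():
    """Flat 20 x 10 x 3 mm cartilage slab over a bone layer, 0.5 mm voxels."""
    return hc.make_slab_phantom(20.0, 10.0, 3.0, voxel_spacing_mm=0.5)


@pytest.fixture(scope="session")
def slab_with_hole():
    return hc.make_slab_phantom(
        20.0, 10.0, 3.0, hole_specs=[(0.0, 0.0, 2.0)], voxel_spacing_mm=0.5
    )


@pytest.fixture(scope="session")
def curved_slab():
    return hc.make_slab_phantom(
        20.0, 10.0, 3.0, curvature_radius_mm=30.0, voxel_spacing_mm=0.5
    )


@pytest.fixture(scope="session")
def condyle():
    """Femoral-style condyle phantom (R=30 mm cylinder, 2 mm cartilage)."""
    return hc.make_joint_phantom("femoral", thickness_mm=2.0)


@pytest.fixture(scope="session")
def tibial_phantom():
    return hc.make_joint_phantom("tibial")


@pytest.fixture(scope="session")
def patellar_phantom():
    return hc.make_joint_phantom("patellar")


@pytest.fixture(scope="session")
def atlas160():
    return hc.make_template_atlas(160)


@pytest.fixture(scope="session")
def slab_sheet(slab):
    """Optimized single-layer sheet of the flat slab (stage-2 complete)."""
    cart = slab.surfaces["cartilage"]
    bone = slab.surfaces["bone"]
    grid = hs.make_sweep_grid(
        cart, "tibial", strategy="rectilinear",
        bone_hint=bone.vertices.view(np.ndarray).mean(axis=0),
    )
    sheet = hs.build_hex_sheet(grid)
    sheet = hs.repair_degenerates(sheet, hs.classify_degenerates(sheet), surface=cart)
    sheet = hs.optimize_quality(sheet, 0.0, surface=cart)
    sheet = hs.subdivide_inplane(sheet, surface=cart)
    return hs.optimize_quality(sheet, 0.5, surface=cart)


@pytest.fixture(scope="session")
def condyle_stage2(condyle):
    """Condyle sheet taken through grid -> repair -> stage-1 -> in-plane
    subdivision -> stage-2 optimization (no blending)."""
    cart = condyle.surfaces["femoral_cartilage"]
    grid = hs.make_sweep_grid(cart, "femoral")
    sheet = hs.build_hex_sheet(grid)
    sheet = hs.repair_degenerates(sheet, hs.classify_degenerates(sheet), surface=cart)
    sheet = hs.trim_boundary_slivers(sheet)
    sheet = hs.optimize_quality(sheet, 0.0, surface=cart)
    sheet = hs.subdivide_inplane(sheet, surface=cart)
    return hs.optimize_quality(sheet, 0.5, surface=cart)


@pytest.fixture(scope="session")
def condyle_mesh(condyle):
    """Condyle meshed end to end with blending and bone fusion."""
    return hs.mesh_cartilage(
        condyle.surfaces["femoral_cartilage"],
        "femoral",
        condyle.surfaces["femur"],
    )
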