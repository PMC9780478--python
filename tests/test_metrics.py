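"""Quality and comparison metrics against closed forms and brute force."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from hexcart import metrics as mx

CUBE = np.array(
    [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
     [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
    dtype=float,
)


def _brute_sj(h):
    B = [(0, 1, 3, 4), (1, 2, 0, 5), (2, 3, 1, 6), (3, 0, 2, 7)]
    T = [(4, 7, 5, 0), (5, 4, 6, 1), (6, 5, 7, 2), (7, 6, 4, 3)]
    best = np.inf
    for k, a, b, c in B + T:
        m = np.array([h[a] - h[k], h[b] - h[k], h[c] - h[k]])
        m = m / np.linalg.norm(m, axis=1, keepdims=True)
        best = min(best, np.linalg.det(m))
    return best


def test_sj_unit_cube_is_one():
    assert mx.scaled_jacobian(CUBE) == pytest.approx(1.0)


def test_sj_inverted_cube_negative():
    inv = CUBE.copy()
    inv[[4, 5]] = inv[[5, 4]]
    assert mx.scaled_jacobian(inv) < 0


@pytest.mark.parametrize("theta_deg", [10, 30, 45, 60])
def test_sj_sheared_cube_matches_brute_force(theta_deg):
    sheared = CUBE.copy()
    sheared[4:, 0] += np.tan(np.deg2rad(theta_deg))
    assert abs(mx.scaled_jacobian(sheared) - _brute_sj(sheared)) < 1e-10
    # analytic: shear by theta drops the corner determinant to cos(theta)
    assert mx.scaled_jacobian(sheared) == pytest.approx(
        np.cos(np.deg2rad(theta_deg)), abs=1e-12
    )


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    angles=st.tuples(*[st.floats(-np.pi, np.pi) for _ in range(3)]),
    scale=st.floats(0.1, 10.0),
)
def test_sj_invariant_under_rigid_and_uniform_scale(angles, scale):
    from scipy.spatial.transform import Rotation

    h = CUBE.copy()
    h[6] += [0.2, -0.1, 0.3]  # arbitrary non-cube element
    R = Rotation.from_euler("xyz", angles).as_matrix()
    moved = scale * h @ R.T + np.array([3.0, -1.0, 2.0])
    assert mx.scaled_jacobian(moved) == pytest.approx(
        mx.scaled_jacobian(h), abs=1e-9
    )


def test_feature_angle_cases():
    verts = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [2, 0, 0], [2, 1, 0]],
        dtype=float,
    )
    faces = np.array([[0, 1, 2, 3], [1, 4, 5, 2]])
    assert mx.feature_angle(verts, faces, (1, 2)) == pytest.approx(0.0, abs=1e-9)
    v_perp = verts.copy()
    v_perp[4:] = [[1, 0, 1], [1, 1, 1]]
    assert mx.feature_angle(v_perp, faces, (1, 2)) == pytest.approx(90.0)
    v_ramp = verts.copy()
    v_ramp[4:] = [[2, 0, 1], [2, 1, 1]]
    assert mx.feature_angle(v_ramp, faces, (1, 2)) == pytest.approx(45.0)


def test_feature_angle_requires_two_faces():
    verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    with pytest.raises(ValueError):
        mx.feature_angle(verts, np.array([[0, 1, 2, 3]]), (0, 1))


def _plane_mesh(z, n=12, extent=10.0, flip=False):
    xs = np.linspace(-extent, extent, n)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    V = np.column_stack([xx.ravel(), yy.ravel(), np.full(n * n, z)])
    F = []
    for i in range(n - 1):
        for j in range(n - 1):
            a, b, c, d = (
                i * n + j, (i + 1) * n + j, (i + 1) * n + j + 1, i * n + j + 1
            )
            F += [[a, b, c], [a, c, d]]
    F = np.asarray(F)
    if flip:
        F = F[:, ::-1]
    return trimesh.Trimesh(V, F, process=False)


def test_deviation_identical_surfaces():
    m = _plane_mesh(0.0)
    rep = mx.surface_deviation(m, m)
    assert rep.coverage == 100.0
    assert rep.distances.max() < 1e-12


def test_deviation_offset_slabs_exact():
    pred = _plane_mesh(0.5)
    ref = _plane_mesh(0.0)
    rep = mx.surface_deviation(pred, ref)
    assert rep.summary["median"] == pytest.approx(0.5, abs=1e-12)
    assert rep.coverage == 100.0


def test_deviation_normal_cutoff_excludes_oblique_rays():
    """Two single-triangle patches whose nearest-point rays deviate 15 and
    25 degrees from the node normals: only the 15-degree one is counted."""
    ref = _plane_mesh(0.0, n=30, extent=30.0)

    def tilted_patch(angle_deg, x0):
        a = np.deg2rad(angle_deg)
        # small triangle above the plane, tilted so its normal deviates
        # from the (vertical) nearest-point ray by the given angle
        base = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float
        )
        R = np.array(
            [[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]]
        )
        V = base @ R.T + [x0, 0, 2.0]
        return V

    for angle, expect_cov in ((15.0, 100.0), (25.0, 0.0)):
        V = tilted_patch(angle, 0.0)
        pred = trimesh.Trimesh(V, np.array([[0, 1, 2]]), process=False)
        rep = mx.surface_deviation(pred, ref, max_normal_dev_deg=20.0)
        assert rep.coverage == pytest.approx(expect_cov)


def test_deviation_kde_integrates_to_one():
    rng = np.random.default_rng(3)
    pred = _plane_mesh(0.5, n=20)
    pred.vertices[:, 2] += rng.normal(scale=0.05, size=len(pred.vertices))
    rep = mx.surface_deviation(pred, _plane_mesh(0.0, n=20))
    grid, dens = rep.kde
    assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)


def test_dice_closed_forms():
    a = np.zeros((10, 10, 10), int)
    a[:5] = 1
    assert mx.dice(a, a, 1) == 1.0
    b = np.zeros_like(a)
    b[5:] = 1
    assert mx.dice(a, b, 1) == 0.0
    # 10^3 cube shifted by 5 voxels: overlap 500 of 1000+1000
    g = np.zeros((20, 30, 30), int)
    g[:10] = 1
    h = np.zeros_like(g)
    h[5:15] = 1
    assert mx.dice(g, h, 1) == pytest.approx(2 * 5 * 30 * 30 / (2 * 10 * 30 * 30))


def test_dice_shape_mismatch_and_empty():
    with pytest.raises(ValueError):
        mx.dice(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)), 1)
    with pytest.raises(ValueError):
        mx.dice(np.zeros((2, 2, 2), int), np.zeros((2, 2, 2), int), 1)


def test_minmax_rms_closed_forms():
    t = np.linspace(0, 1, 100)
    ref = 3.0 * np.sin(2 * np.pi * t) + 1.0
    assert mx.minmax_rms(ref, ref) == (0.0, 0.0)
    rms, pct = mx.minmax_rms(ref, ref + 0.6)
    assert rms == pytest.approx(0.6)
    assert pct == pytest.approx(100 * 0.6 / (ref.max() - ref.min()))


def test_minmax_percentage_affine_invariant():
    t = np.linspace(0, 1, 64)
    a = np.cos(2 * np.pi * t)
    b = a + np.sin(7 * t) * 0.2
    _, pct = mx.minmax_rms(a, b)
    _, pct2 = mx.minmax_rms(5.0 * a - 2.0, 5.0 * b - 2.0)
    assert pct2 == pytest.approx(pct, rel=1e-12)
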