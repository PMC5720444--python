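import numpy as np
import pytest

from regqa import (
    BSplineTransform,
    FrameGeometry,
    NumericalInverse,
    PointSet,
    UniformTranslation,
    Volume,
    compose_residual,
    identity_transform,
    random_transform,
    scale_transform,
    true_de,
    true_de_dense,
    warp_volume,
)
from regqa.bspline import _covering_grid

from conftest import make_smooth_volume


def _textbook_b3(x: float) -> float:
    """Centered uniform cubic B-spline kernel, straight from its piecewise
    definition (independent of the evaluation code under test)."""
    x = abs(x)
    if x < 1.0:
        return (4.0 - 6.0 * x**2 + 3.0 * x**3) / 6.0
    if x < 2.0:
        return (2.0 - x) ** 3 / 6.0
    return 0.0


def _textbook_displacement(t: BSplineTransform, p) -> np.ndarray:
    """Direct triple sum over all control points with the textbook kernel."""
    out = np.zeros(3)
    mx, my, mz = t.grid_shape
    for a in range(mx):
        for b in range(my):
            for c in range(mz):
                w = 1.0
                for axis, idx in zip(range(3), (a, b, c)):
                    pos = t.control_origin[axis] + idx * t.control_spacing[axis]
                    w *= _textbook_b3((p[axis] - pos) / t.control_spacing[axis])
                out += w * t.coefficients[a, b, c]
    return out


@pytest.fixture
def frame() -> FrameGeometry:
    return FrameGeometry((40, 40, 12), (2.0, 2.0, 5.0))


def test_zero_coefficients_give_zero_displacement(frame, rng):
    t = identity_transform(frame, 8.0)
    pts = rng.uniform([0, 0, 0], [78, 78, 55], size=(50, 3))
    np.testing.assert_array_equal(t.displacement_at(pts), np.zeros((50, 3)))


def test_partition_of_unity_constant_coefficients(frame, rng):
    origin, shape = _covering_grid(frame, 8.0)
    coeff = np.zeros(shape + (3,))
    coeff[...] = (3.0, -1.5, 2.0)
    t = BSplineTransform(origin, (8.0,) * 3, coeff)
    pts = rng.uniform(t.support_lo + 16.0, t.support_hi - 16.0, size=(100, 3))
    np.testing.assert_allclose(t.displacement_at(pts), np.tile([3.0, -1.5, 2.0], (100, 1)), atol=1e-12)


def test_single_coefficient_matches_textbook_basis(frame):
    origin, shape = _covering_grid(frame, 8.0)
    coeff = np.zeros(shape + (3,))
    a, b, c = 4, 5, 3
    coeff[a, b, c] = (2.0, 0.0, -1.0)
    t = BSplineTransform(origin, (8.0,) * 3, coeff)
    cp = origin + np.array([a, b, c]) * 8.0
    # at the control point itself and at off-grid probes nearby
    for p in (cp, cp + [3.1, -2.2, 0.7], cp + [7.9, 0.0, -5.0]):
        np.testing.assert_allclose(t.displacement_at(p), _textbook_displacement(t, p), atol=1e-12)


def test_linearity_under_scaling(frame, rng):
    t = random_transform(frame, 8.0, 3.0, seed=3)
    pts = rng.uniform([4, 4, 5], [74, 74, 50], size=(100, 3))
    base = t.displacement_at(pts)
    for factor in (0.0, 0.5, 1.0, 2.5):
        ts = scale_transform(t, factor)
        np.testing.assert_allclose(ts.displacement_at(pts), factor * base, atol=1e-9)
    with pytest.raises(ValueError):
        scale_transform(t, -1.0)


def test_random_transform_determinism_and_identity(frame):
    t1 = random_transform(frame, 8.0, 5.0, seed=11)
    t2 = random_transform(frame, 8.0, 5.0, seed=11)
    np.testing.assert_array_equal(t1.coefficients, t2.coefficients)
    t0 = random_transform(frame, 8.0, 0.0, seed=11)
    assert np.all(t0.coefficients == 0.0)
    with pytest.raises(ValueError):
        random_transform(frame, -1.0, 5.0, seed=0)
    with pytest.raises(ValueError, match="4x"):
        random_transform(frame, 4.0, 5.0, seed=0)  # below 4x in-plane spacing


def test_random_transform_vanishes_at_volume_faces(frame):
    t = random_transform(frame, 8.0, 5.0, seed=5)
    lo, hi = frame.center_bbox_mm
    face_pts = []
    edges = np.linspace(0.0, 1.0, 7)
    for fx in (lo[0], hi[0]):
        for fy in edges:
            for fz in edges:
                face_pts.append([fx, lo[1] + fy * (hi[1] - lo[1]), lo[2] + fz * (hi[2] - lo[2])])
    np.testing.assert_allclose(t.displacement_at(np.array(face_pts)), 0.0, atol=1e-12)


def test_mean_displacement_grows_with_amplitude(frame, rng):
    pts = rng.uniform([8, 8, 10], [70, 70, 45], size=(200, 3))
    means = []
    for amp in (1.0, 2.0, 3.0, 4.0, 5.0):
        t = random_transform(frame, 8.0, amp, seed=9)
        means.append(np.linalg.norm(t.displacement_at(pts), axis=1).mean())
    assert all(b > a for a, b in zip(means, means[1:]))


def test_true_de_examples(frame, rng):
    t = identity_transform(frame, 8.0)
    pts = PointSet(rng.uniform([5, 5, 5], [70, 70, 50], size=(10, 3)), np.arange(10), frame)
    assert true_de(t, pts) == (0.0, 0.0)

    origin, shape = _covering_grid(frame, 8.0)
    coeff = np.zeros(shape + (3,))
    coeff[...] = (3.0, 4.0, 0.0)
    t_const = BSplineTransform(origin, (8.0,) * 3, coeff)
    de, axial = true_de(t_const, pts)
    assert de == pytest.approx(5.0, abs=1e-9)
    assert axial == pytest.approx(5.0, abs=1e-9)

    with pytest.raises(ValueError, match="empty"):
        true_de(t, np.empty((0, 3)))


def test_true_de_matches_bruteforce_oracle(frame, rng):
    t = random_transform(frame, 8.0, 3.0, seed=21)
    pts = rng.uniform([5, 5, 5], [70, 70, 50], size=(10, 3))
    de, axial = true_de(t, pts)
    sq3 = sq2 = 0.0
    for p in pts:  # brute-force per-point evaluation of the RMS definition
        d = t.displacement_at(p)
        sq3 += d[0] ** 2 + d[1] ** 2 + d[2] ** 2
        sq2 += d[0] ** 2 + d[1] ** 2
    assert de == pytest.approx(np.sqrt(sq3 / 10), abs=1e-9)
    assert axial == pytest.approx(np.sqrt(sq2 / 10), abs=1e-9)


def test_true_de_invariant_under_relabeling(frame, rng):
    t = random_transform(frame, 8.0, 3.0, seed=2)
    pts = rng.uniform([5, 5, 5], [70, 70, 50], size=(30, 3))
    perm = rng.permutation(30)
    a = true_de(t, PointSet(pts, np.arange(30), frame))
    b = true_de(t, PointSet(pts[perm], np.arange(30), frame))
    assert a == pytest.approx(b, abs=1e-12)


def test_true_de_dense_matches_pointwise(frame):
    t = random_transform(frame, 8.0, 3.0, seed=4)
    centers = frame.voxel_centers().reshape(-1, 3)
    expected = true_de(t, centers)
    got = true_de_dense(t, frame, x_chunk=7)
    assert got == pytest.approx(expected, abs=1e-9)


def test_warp_identity_is_bit_exact(frame, rng):
    v = Volume(rng.normal(size=frame.shape), frame.spacing, frame.origin)
    w = warp_volume(v, identity_transform(frame, 8.0))
    np.testing.assert_array_equal(w.data, v.data)


def test_warp_integer_translation_matches_shift(frame, rng):
    v = Volume(rng.normal(size=frame.shape), frame.spacing, frame.origin)
    origin, shape = _covering_grid(frame, 8.0)
    coeff = np.zeros(shape + (3,))
    coeff[...] = (2 * 2.0, 0.0, 0.0)  # exactly two voxels in +x
    t = BSplineTransform(origin, (8.0,) * 3, coeff)
    w = warp_volume(v, t)
    # forward +x by 2 voxels: output voxel i came from input voxel i-2
    np.testing.assert_allclose(w.data[2:, :, :], v.data[:-2, :, :], atol=1e-9)


def test_warp_preserves_mean_intensity_of_smooth_image(frame):
    v = make_smooth_volume(frame, seed=3)
    t = random_transform(frame, 8.0, 2.0, seed=6, smooth_sigma=1.0)
    w = warp_volume(v, t)
    interior = (slice(6, -6), slice(6, -6), slice(2, -2))
    assert np.mean(w.data[interior]) == pytest.approx(np.mean(v.data[interior]), rel=0.01)


def test_compose_residual_identity_equals_true_de(frame, rng):
    t = random_transform(frame, 8.0, 2.0, seed=8)
    pts = rng.uniform([8, 8, 10], [70, 70, 45], size=(40, 3))
    ident = identity_transform(frame, 8.0)
    assert compose_residual(t, ident, pts) == pytest.approx(true_de(t, pts), abs=1e-12)


def test_compose_residual_exact_inverse_translation(frame, rng):
    pts = rng.uniform([8, 8, 10], [66, 66, 45], size=(40, 3))
    fwd = UniformTranslation((2.0, 0.0, 0.0))
    back = UniformTranslation((-2.0, 0.0, 0.0))
    assert compose_residual(fwd, back, pts) == pytest.approx((0.0, 0.0), abs=1e-12)


def test_compose_residual_matches_pointwise_oracle(frame, rng):
    t0 = random_transform(frame, 8.0, 2.0, seed=13)
    t1 = random_transform(frame, 8.0, 1.0, seed=14)
    pts = rng.uniform([10, 10, 10], [66, 66, 45], size=(25, 3))
    de, axial = compose_residual(t0, t1, pts)
    sq3 = sq2 = 0.0
    for p in pts:
        y = p + t0.displacement_at(p)
        z = y + t1.displacement_at(y)
        e = z - p
        sq3 += e @ e
        sq2 += e[0] ** 2 + e[1] ** 2
    assert de == pytest.approx(np.sqrt(sq3 / 25), abs=1e-9)
    assert axial == pytest.approx(np.sqrt(sq2 / 25), abs=1e-9)


def test_numerical_inverse_recovers_preimage(frame, rng):
    t = random_transform(frame, 8.0, 2.0, seed=17, smooth_sigma=1.0)
    inv = NumericalInverse(t, tol=1e-4, max_iter=50)
    x = rng.uniform([10, 10, 10], [66, 66, 45], size=(30, 3))
    y = x + t.displacement_at(x)
    x_back = y + inv.displacement_at(y)
    np.testing.assert_allclose(x_back, x, atol=1e-3)
    assert inv.inverse() is t


def test_displacement_outside_support_raises(frame):
    t = random_transform(frame, 8.0, 2.0, seed=1)
    with pytest.raises(ValueError, match="support"):
        t.displacement_at(np.array([[1e4, 0.0, 0.0]]))


def test_transform_json_roundtrip(tmp_path, frame):
    t = random_transform(frame, 8.0, 3.0, seed=30)
    path = t.save(tmp_path / "t.json")
    back = BSplineTransform.load(path)
    np.testing.assert_array_equal(back.coefficients, t.coefficients)
    np.testing.assert_array_equal(back.control_origin, t.control_origin)
    np.testing.assert_array_equal(back.control_spacing, t.control_spacing)
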