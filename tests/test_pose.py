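import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fetalpose.brainmask import BrainEllipsoid
from fetalpose.pose import (CollinearLandmarks, apply_tilt, build_frame,
                            frame_to_transform, resolve_left_right)

B = np.zeros(3)
E1 = np.array([-10.0, 20.0, 0.0])
E2 = np.array([10.0, 20.0, 0.0])


def frame_matrix(frame):
    return np.stack([frame.lr, frame.pa, frame.is_])


def assert_orthonormal(frame):
    m = frame_matrix(frame)
    np.testing.assert_allclose(m @ m.T, np.eye(3), atol=1e-9)
    assert np.linalg.det(m) == pytest.approx(1.0, abs=1e-9)


class TestBuildFrame:
    def test_axis_aligned_symmetric(self):
        f = build_frame(B, E1, E2)
        np.testing.assert_allclose(f.pa, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(f.lr, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(f.is_, [0, 0, 1], atol=1e-12)
        assert_orthonormal(f)

    def test_eye_swap_negates_lr_and_is(self):
        f = build_frame(B, E1, E2)
        g = build_frame(B, E2, E1)
        np.testing.assert_allclose(g.lr, -f.lr, atol=1e-12)
        np.testing.assert_allclose(g.is_, -f.is_, atol=1e-12)
        np.testing.assert_allclose(g.pa, f.pa, atol=1e-12)

    def test_orthonormalization_branch(self):
        e1 = np.array([-10.0, 18.0, 2.0])
        e2 = np.array([10.0, 22.0, -2.0])
        f = build_frame(B, e1, e2)
        assert_orthonormal(f)
        lr0 = (e2 - e1) / np.linalg.norm(e2 - e1)
        assert abs(np.dot(f.lr, f.pa)) < 1e-12
        assert float(np.dot(f.lr, lr0)) < 1.0 - 1e-6  # LR was adjusted

    def test_collinear_rejected(self):
        with pytest.raises(CollinearLandmarks):
            build_frame(B, np.array([1.0, 0, 0]), np.array([2.0, 0, 0]))


class TestApplyTilt:
    def test_zero_tilt_identity(self):
        f = build_frame(B, E1, E2)
        g = apply_tilt(f, 0.0)
        np.testing.assert_allclose(frame_matrix(g), frame_matrix(f),
                                   atol=1e-12)

    def test_thirty_degree_rotation_of_pa(self):
        f = build_frame(B, E1, E2)
        g = apply_tilt(f, 30.0)
        cosang = float(np.dot(f.pa, g.pa))
        assert math.degrees(math.acos(cosang)) == pytest.approx(30.0,
                                                                abs=1e-9)
        np.testing.assert_allclose(g.lr, f.lr, atol=1e-12)
        assert_orthonormal(g)

    def test_tilt_composition(self):
        f = build_frame(B, E1, E2)
        once = apply_tilt(f, 30.0)
        twice = apply_tilt(apply_tilt(f, 15.0), 15.0)
        np.testing.assert_allclose(frame_matrix(once), frame_matrix(twice),
                                   atol=1e-9)


def eye_points():
    # exact 30-degree tilt geometry: |mid| = 40 mm, half-separation 14 mm
    import math
    mid = 40.0 * np.array([0.0, math.cos(math.radians(30.0)),
                           -math.sin(math.radians(30.0))])
    return mid + np.array([-14.0, 0.0, 0.0]), mid + np.array([14.0, 0.0, 0.0])


def brain_ellipsoid(major_dir, center=None, anisotropy=1.3):
    major_dir = np.asarray(major_dir, float)
    major_dir = major_dir / np.linalg.norm(major_dir)
    other = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(other, major_dir)) > 0.9:
        other = np.array([1.0, 0.0, 0.0])
    b2 = np.cross(major_dir, other)
    b2 /= np.linalg.norm(b2)
    b3 = np.cross(major_dir, b2)
    dirs = np.stack([major_dir, b2, b3], axis=1)
    axes = np.array([90.0, 90.0 / anisotropy, 90.0 / anisotropy])
    return BrainEllipsoid(center=np.zeros(3) if center is None else center,
                          axes_mm=axes, directions=dirs)


class TestResolveLeftRight:
    def test_correct_lr_kept(self):
        # eyes anterior-inferior, major axis along PA: IS must point away
        # from the eye half-space
        e1, e2 = eye_points()
        f = build_frame(B, e1, e2)
        ell = brain_ellipsoid([0.0, 1.0, 0.0])
        g = resolve_left_right(f, ell, e1, e2, B)
        assert not g.ambiguous
        np.testing.assert_allclose(g.labels["left"], e1)
        np.testing.assert_allclose(g.labels["right"], e2)
        tilted = apply_tilt(g, 30.0)
        np.testing.assert_allclose(tilted.is_, [0, 0, 1], atol=1e-6)

    def test_swapped_input_recovers_same_frame(self):
        e1, e2 = eye_points()
        ell = brain_ellipsoid([0.0, 1.0, 0.0])
        g1 = resolve_left_right(build_frame(B, e1, e2), ell, e1, e2, B)
        g2 = resolve_left_right(build_frame(B, e2, e1), ell, e2, e1, B)
        np.testing.assert_allclose(frame_matrix(g1), frame_matrix(g2),
                                   atol=1e-9)
        np.testing.assert_allclose(g1.labels["left"], g2.labels["left"])

    def test_spherical_brain_is_ambiguous(self):
        e1, e2 = eye_points()
        f = build_frame(B, e1, e2)
        ell = brain_ellipsoid([0.0, 1.0, 0.0], anisotropy=1.01)
        ell.isotropic = True
        g = resolve_left_right(f, ell, e1, e2, B)
        assert g.ambiguous and g.labels is None

    def test_major_axis_near_lr_is_ambiguous(self):
        e1, e2 = eye_points()
        f = build_frame(B, e1, e2)
        ell = brain_ellipsoid([1.0, 0.05, 0.0])
        g = resolve_left_right(f, ell, e1, e2, B)
        assert g.ambiguous


class TestFrameToTransform:
    def test_axis_aligned_identity_rotation(self):
        f = build_frame(B, E1, E2)
        rec = frame_to_transform(f)
        np.testing.assert_allclose(rec["transform"][:3, :3], np.eye(3),
                                   atol=1e-12)
        np.testing.assert_allclose(rec["transform"][:3, 3], 0.0, atol=1e-12)

    def test_eyes_share_axial_plane(self):
        e1 = np.array([-9.0, 25.0, 4.0])
        e2 = np.array([12.0, 23.0, -3.0])
        f = build_frame(B, e1, e2)
        t = frame_to_transform(f)["transform"]
        z1 = (t @ np.append(e1, 1.0))[2]
        z2 = (t @ np.append(e2, 1.0))[2]
        assert z1 == pytest.approx(z2, abs=1e-9)

    def test_rotation_block_orthogonal(self):
        f = apply_tilt(build_frame(B, E1, E2), 30.0)
        r = frame_to_transform(f)["transform"][:3, :3]
        np.testing.assert_allclose(r.T @ r, np.eye(3), atol=1e-9)


class TestTiltResolveOrder:
    def test_resolve_then_tilt_equals_tilt_then_resolve(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            rot = Rotation.random(rng=rng)
            e1_0, e2_0 = eye_points()
            e1, e2 = rot.apply(e1_0), rot.apply(e2_0)
            ell = brain_ellipsoid(rot.apply([0.0, 1.0, 0.0]))
            f = build_frame(B, e1, e2)
            a = apply_tilt(resolve_left_right(f, ell, e1, e2, B), 30.0)
            b = resolve_left_right(apply_tilt(f, 30.0), ell, e1, e2, B)
            np.testing.assert_allclose(frame_matrix(a), frame_matrix(b),
                                       atol=1e-9)
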