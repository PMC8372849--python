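import numpy as np
import pytest

from fetalpose.localize import (BrainNotFound, RegionCluster, assign_members,
                                brain_center, fill_factor,
                                fit_ellipsoid_voxels, mean_shift_modes,
                                regularize_slices, select_brain)
from fetalpose.mser import ExtremalRegion

OFD = 96.0


def make_region(xyz, slice_index=0):
    r = ExtremalRegion(pixels=np.array([[0, 0], [0, 1], [1, 0]]),
                       slice_index=slice_index)
    r.barycenter_world = np.asarray(xyz, dtype=float)
    return r


class TestMeanShift:
    def test_single_point_is_fixed_point(self):
        modes = mean_shift_modes(np.array([[3.0, -2.0, 5.0]]),
                                 kernel_fwhm=48.0, tol=0.5)
        assert len(modes) == 1
        np.testing.assert_allclose(modes[0], [3.0, -2.0, 5.0], atol=0.5)

    def test_two_separated_groups_give_two_modes(self):
        rng = np.random.default_rng(2)
        g1 = rng.normal([0, 0, 0], 1.0, size=(5, 3))
        g2 = rng.normal([160.0, 0, 0], 1.0, size=(5, 3))  # 4 x FWHM apart
        modes = mean_shift_modes(np.vstack([g1, g2]), kernel_fwhm=40.0,
                                 grid_spacing=20.0, tol=0.5)
        assert len(modes) == 2
        d1 = min(np.linalg.norm(m - g1.mean(0)) for m in modes)
        d2 = min(np.linalg.norm(m - g2.mean(0)) for m in modes)
        assert d1 < 1.0 and d2 < 1.0

    def test_short_segment_collapses_to_center(self):
        pts = np.stack([np.linspace(0, 4.0, 9), np.zeros(9), np.zeros(9)],
                       axis=1)  # length 0.1 x FWHM
        modes = mean_shift_modes(pts, kernel_fwhm=40.0, tol=0.5)
        assert len(modes) == 1
        np.testing.assert_allclose(modes[0], [2.0, 0.0, 0.0], atol=0.5)

    def test_no_points_empty(self):
        assert mean_shift_modes(np.empty((0, 3)), kernel_fwhm=40.0).size == 0

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(-40, 40, size=(12, 3))
        shift = np.array([103.0, -55.0, 20.0])
        m1 = mean_shift_modes(pts, kernel_fwhm=50.0, tol=0.5)
        m2 = mean_shift_modes(pts + shift, kernel_fwhm=50.0, tol=0.5)
        assert len(m1) == len(m2)
        m1s = sorted(map(tuple, m1 + shift))
        m2s = sorted(map(tuple, m2))
        np.testing.assert_allclose(m1s, m2s, atol=1.0)


class TestAssignMembers:
    def test_strict_radius(self):
        mode = np.zeros((1, 3))
        inside = make_region([0.49 * OFD, 0, 0])
        boundary = make_region([0.5 * OFD, 0, 0])
        clusters = assign_members([inside, boundary], mode, OFD)
        assert len(clusters) == 1
        assert clusters[0].members == [inside]

    def test_multi_membership(self):
        modes = np.array([[0.0, 0, 0], [40.0, 0, 0]])
        shared = make_region([20.0, 0, 0])
        clusters = assign_members([shared], modes, OFD)
        assert len(clusters) == 2
        assert all(shared in c.members for c in clusters)

    def test_empty_clusters_dropped(self):
        modes = np.array([[0.0, 0, 0], [500.0, 0, 0]])
        clusters = assign_members([make_region([1.0, 0, 0])], modes, OFD)
        assert len(clusters) == 1


def ball_mask(shape=(24, 24, 24), center=(12, 12, 12), r=8):
    g = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"),
                 axis=-1).astype(float)
    return np.linalg.norm(g - np.array(center), axis=-1) <= r


class TestFillFactor:
    def test_self_fit_mask_scores_its_volume(self):
        mask = fit_ellipsoid_voxels(ball_mask())
        c = RegionCluster(members=[], centroid=np.zeros(3), mask=mask)
        f = fill_factor(c)
        inter = np.count_nonzero(mask)
        # E fitted to its own rasterization: |E \ M| nearly empty
        assert f >= 0.9 * inter

    def test_half_ellipsoid_scores_near_zero(self):
        full = ball_mask(r=9)
        half = full.copy()
        half[12:, :, :] = False
        c = RegionCluster(members=[], centroid=np.zeros(3), mask=half)
        f = fill_factor(c)
        assert abs(f) <= 0.35 * np.count_nonzero(full)

    def test_tiny_mask_gets_sentinel(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2, 2, 2] = mask[2, 2, 3] = mask[2, 3, 2] = True
        c = RegionCluster(members=[], centroid=np.zeros(3), mask=mask)
        assert fill_factor(c) == -np.inf


class TestSelectBrain:
    def test_brainlike_beats_flat_cluster(self):
        ball = RegionCluster(members=[], centroid=np.zeros(3),
                             mask=ball_mask(r=8))
        flat = np.zeros((24, 24, 24), dtype=bool)
        flat[4:20, 4:20, 11] = True
        flat_c = RegionCluster(members=[], centroid=np.ones(3), mask=flat)
        assert select_brain([ball, flat_c]) is ball

    def test_single_cluster_returned(self):
        c = RegionCluster(members=[], centroid=np.zeros(3),
                          mask=ball_mask(r=6))
        assert select_brain([c]) is c

    def test_no_clusters_raises(self):
        with pytest.raises(BrainNotFound):
            select_brain([])


class TestRegularize:
    def test_interior_hole_filled(self):
        m = np.zeros((10, 10, 3), dtype=bool)
        m[2:8, 2:8, 1] = True
        m[5, 5, 1] = False
        out = regularize_slices(m, slice_axis=2)
        assert out[5, 5, 1]

    def test_empty_slice_between_identical_disks(self):
        m = np.zeros((12, 12, 5), dtype=bool)
        disk = ball_mask(shape=(12, 12, 1), center=(6, 6, 0), r=4)[:, :, 0]
        m[:, :, 1] = disk
        m[:, :, 3] = disk
        out = regularize_slices(m, slice_axis=2)
        np.testing.assert_array_equal(out[:, :, 2], disk)

    def test_protrusion_removed(self):
        m = np.zeros((12, 12, 5), dtype=bool)
        disk = ball_mask(shape=(12, 12, 1), center=(6, 6, 0), r=3)[:, :, 0]
        for k in (1, 2, 3):
            m[:, :, k] = disk
        m[0, 0, 2] = True  # voxel absent from both neighbours
        out = regularize_slices(m, slice_axis=2)
        assert not out[0, 0, 2]
        np.testing.assert_array_equal(out[:, :, 2], disk)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_idempotent_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((14, 14, 9)) < 0.25
        once = regularize_slices(m, slice_axis=2)
        twice = regularize_slices(once, slice_axis=2)
        np.testing.assert_array_equal(once, twice)


class TestBrainCenter:
    def test_centered_ball(self):
        mask = ball_mask()
        center = brain_center(mask, lambda idx: idx.astype(float))
        np.testing.assert_allclose(center, [12, 12, 12], atol=0.5)

    def test_two_voxel_midpoint(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[0, 0, 0] = m[4, 0, 0] = True
        center = brain_center(m, lambda idx: idx.astype(float))
        np.testing.assert_allclose(center, [2, 0, 0])

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            brain_center(np.zeros((3, 3, 3), dtype=bool),
                         lambda idx: idx.astype(float))

    def test_phantom_brain_center_accuracy(self, clean_detection,
                                           biometry_table):
        result, truth = clean_detection
        ofd = truth.biometry[0]
        assert np.linalg.norm(result.b - truth.b) <= 0.1 * ofd
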