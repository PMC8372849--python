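import math

import numpy as np
import pytest

from fetalpose.mser import ExtremalRegion
from fetalpose.regions import (FILTER_STAGES, EllipseFit, RibbonOutOfBounds,
                               apply_filters, fit_ellipse, local_contrast,
                               rasterize_ellipse)

BIO = (96.0, 79.0, 14.0)  # OFD, BPD, OD at 31 weeks


def disk_region(radius_px, center=(40, 40), shape=(80, 80)):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px ** 2
    return ExtremalRegion(pixels=np.argwhere(mask))


def ellipse_region(a_px, b_px, center=(40, 40), shape=(80, 80)):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    mask = ((yy - center[0]) / a_px) ** 2 + ((xx - center[1]) / b_px) ** 2 <= 1
    return ExtremalRegion(pixels=np.argwhere(mask))


class TestFitEllipse:
    def test_disk_axes_and_dice(self):
        fit = fit_ellipse(disk_region(10), (1.0, 1.0), (80, 80))
        assert fit.a == pytest.approx(20.0, rel=0.03)
        assert fit.b == pytest.approx(20.0, rel=0.03)
        assert fit.dice >= 0.98

    def test_two_to_one_ellipse_aspect(self):
        fit = fit_ellipse(ellipse_region(20, 10), (1.0, 1.0), (80, 80))
        assert fit.aspect_ratio == pytest.approx(2.0, rel=0.05)

    def test_region_equal_to_own_ellipse_mask_has_high_dice(self):
        fit0 = fit_ellipse(disk_region(12), (1.0, 1.0), (80, 80))
        mask = rasterize_ellipse(fit0, (1.0, 1.0), (80, 80))
        region = ExtremalRegion(pixels=np.argwhere(mask))
        fit = fit_ellipse(region, (1.0, 1.0), (80, 80))
        assert fit.dice >= 0.99

    def test_axes_scale_with_spacing(self):
        f1 = fit_ellipse(disk_region(10), (1.0, 1.0), (80, 80))
        f2 = fit_ellipse(disk_region(10), (2.0, 2.0), (80, 80))
        assert f2.a == pytest.approx(2 * f1.a, rel=1e-6)
        assert f2.area_mm2 == pytest.approx(4 * f1.area_mm2, rel=1e-6)

    def test_area_consistent_with_axes(self):
        fit = fit_ellipse(ellipse_region(15, 9), (1.0, 1.0), (80, 80))
        assert fit.area_mm2 == pytest.approx(
            math.pi * fit.a * fit.b / 4.0, rel=1e-6)

    def test_collinear_pixels_flagged_degenerate(self):
        region = ExtremalRegion(pixels=np.array([[5, c] for c in range(5, 15)]))
        fit = fit_ellipse(region, (1.0, 1.0), (20, 20))
        assert fit.degenerate and fit.b == pytest.approx(1.0)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipse(ExtremalRegion(pixels=np.array([[0, 0], [0, 1]])),
                        (1.0, 1.0))


class TestLocalContrast:
    def test_uniform_slice_gives_unity(self):
        region = disk_region(8)
        c = local_contrast(region, np.full((80, 80), 50.0), (1.0, 1.0))
        assert c == pytest.approx(1.0)

    def test_disk_over_ground_ratio(self):
        region = disk_region(8)
        img = np.full((80, 80), 100.0)
        img[tuple(region.pixels.T)] = 300.0
        assert local_contrast(region, img, (1.0, 1.0)) == pytest.approx(3.0)

    def test_corner_region_rejected(self):
        region = disk_region(6, center=(0, 0), shape=(40, 40))
        region.pixels = region.pixels[:7]  # collapse to the very corner
        fit = fit_ellipse(region, (1.0, 1.0), (40, 40))
        # force the ellipse fully outside the slice
        fit = EllipseFit(np.array([-50.0, -50.0]), fit.a, fit.b,
                         fit.orientation, fit.area_mm2, fit.dice)
        with pytest.raises(RibbonOutOfBounds):
            local_contrast(region, np.ones((40, 40)), (1.0, 1.0), fit=fit)


def make_fit(area_norm=1.0, aspect_norm=1.0, major_norm=1.0, dice=1.0,
             stage="brain_localize", center=(0.0, 0.0)):
    ofd, bpd, od = BIO
    a_ref, b_ref = (od, od) if stage == "eye" else (ofd, bpd)
    a = major_norm * a_ref
    b = a / (aspect_norm * (a_ref / b_ref))
    area = area_norm * math.pi * (a_ref / 2) * (b_ref / 2)
    return EllipseFit(np.asarray(center, float), a, b, 0.0, area, dice)


def dummy_region(dist_norm=None):
    ofd = BIO[0]
    r = ExtremalRegion(pixels=np.array([[0, 0], [0, 1], [1, 0]]))
    if dist_norm is not None:
        r.barycenter_world = np.array([dist_norm * ofd / 2.0, 0.0, 0.0])
    return r


class TestApplyFilters:
    def test_ideal_region_kept_at_stage_a(self):
        stage = FILTER_STAGES["brain_localize"]
        kept = apply_filters([dummy_region()], stage, BIO,
                             fits=[make_fit()])
        assert len(kept) == 1

    def test_major_axis_above_bound_rejected(self):
        stage = FILTER_STAGES["brain_localize"]
        kept = apply_filters([dummy_region()], stage, BIO,
                             fits=[make_fit(major_norm=1.15)])
        assert kept == []

    def test_area_stage_dependence(self):
        # normalized area 0.10 fails stage A (min 0.2), passes stage B
        fit = make_fit(area_norm=0.10)
        region = dummy_region(dist_norm=0.5)
        kept_a = apply_filters([region], FILTER_STAGES["brain_localize"],
                               BIO, fits=[fit])
        kept_b = apply_filters([region], FILTER_STAGES["brain_mask"], BIO,
                               brain_center=np.zeros(3), fits=[fit])
        assert kept_a == [] and len(kept_b) == 1

    def test_eye_contrast_bound(self):
        # C = 1.5 must fail the eye stage (min 2)
        stage = FILTER_STAGES["eye"]
        region = disk_region(4, center=(20, 20), shape=(40, 40))
        region.slice_index = 0
        region.barycenter_world = np.array([BIO[0] / 2.0, 0.0, 0.0])
        img = np.full((40, 40), 100.0)
        img[tuple(region.pixels.T)] = 150.0
        fit = make_fit(stage="eye", major_norm=4 * 2 / BIO[2],
                       aspect_norm=1.0, center=(20.0, 20.0))
        kept = apply_filters([region], stage, BIO,
                             brain_center=np.zeros(3), slices={0: img},
                             spacing=(1.0, 1.0), fits=[fit])
        assert kept == []
        img[tuple(region.pixels.T)] = 300.0
        kept = apply_filters([region], stage, BIO,
                             brain_center=np.zeros(3), slices={0: img},
                             spacing=(1.0, 1.0), fits=[fit])
        assert len(kept) == 1

    def test_distance_requires_brain_center(self):
        with pytest.raises(ValueError, match="brain center"):
            apply_filters([dummy_region()], FILTER_STAGES["brain_mask"],
                          BIO, fits=[make_fit()])

    def test_loosening_a_bound_never_shrinks_kept_set(self):
        rng = np.random.default_rng(0)
        fits = [make_fit(area_norm=rng.uniform(0.05, 1.3),
                         aspect_norm=rng.uniform(0.8, 1.8),
                         major_norm=rng.uniform(0.5, 1.3),
                         dice=rng.uniform(0.5, 1.0)) for _ in range(30)]
        regions = [dummy_region() for _ in fits]
        stage = FILTER_STAGES["brain_localize"]
        base = apply_filters(regions, stage, BIO, fits=fits)
        for loosened in (stage.replace(area_min=0.1),
                         stage.replace(area_max=1.5),
                         stage.replace(aspect_max=2.5),
                         stage.replace(major_max=1.5),
                         stage.replace(dice_min=0.4)):
            wider = apply_filters(regions, loosened, BIO, fits=fits)
            assert set(map(id, base)) <= set(map(id, wider))
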