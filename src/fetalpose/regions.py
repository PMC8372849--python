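"""Ellipse descriptors, the age-specific filter banks and local contrast.

Each detected region is summarized by the equal-moment ellipse of its pixel
set (second central moments), measured in mm. The three filter stages —
global brain localization (A), local brain masking (B) and eye detection
(C) — bound dimensionless ratios of these descriptors against the reference
diameters OFD/BPD (brain) or OD (eyes):

====================  =======  =======  =======  =======  =======  =======
quantity                (A)min   (A)max   (B)min   (B)max   (C)min   (C)max
--------------------  -------  -------  -------  -------  -------  -------
A / (pi aref/2 bref/2)    0.2      1.1     0.05      1.1      0.5      1.2
r / (aref/bref)             -      1.5        -      1.5        -      1.5
a / aref                    -      1.1        -      1.2        -      1.3
Dice D                    0.7        -      0.7        -      0.9        -
d_brain / (OFD/2)           -        -        -      1.1      0.6      1.3
contrast C                  -        -        -        -        2        -
====================  =======  =======  =======  =======  =======  =======

with aref = OFD, bref = BPD for the brain stages and aref = bref = OD for
the eyes. Area is normalized by the reference ellipse area, distance from
the brain centre by OFD/2, making every bound O(1) and dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

import numpy as np

from .mser import ExtremalRegion

__all__ = ["EllipseFit", "FilterStage", "FILTER_STAGES", "fit_ellipse",
           "rasterize_ellipse", "local_contrast", "apply_filters"]


@dataclass
class EllipseFit:
    """Equal-moment ellipse of a pixel set.

    ``a`` and ``b`` are the full major/minor axis lengths in mm,
    ``orientation`` the major-axis angle in radians (in-slice), ``area_mm2``
    the ellipse area, and ``dice`` the overlap between the region mask and
    the rasterized ellipse. ``degenerate`` flags collinear pixel sets whose
    minor axis was floored at one pixel width.
    """

    center: np.ndarray
    a: float
    b: float
    orientation: float
    area_mm2: float
    dice: float
    degenerate: bool = False

    @property
    def aspect_ratio(self) -> float:
        return self.a / self.b


@dataclass
class FilterStage:
    """Bounds of one filter-bank column; ``None`` disables a bound."""

    stage: str
    area_min: float | None = None
    area_max: float | None = None
    aspect_max: float | None = None
    major_max: float | None = None
    dice_min: float | None = None
    dist_min: float | None = None
    dist_max: float | None = None
    contrast_min: float | None = None

    def replace(self, **kw) -> "FilterStage":
        return replace(self, **kw)


FILTER_STAGES: dict[str, FilterStage] = {
    "brain_localize": FilterStage("brain_localize", area_min=0.2, area_max=1.1,
                                  aspect_max=1.5, major_max=1.1, dice_min=0.7),
    "brain_mask": FilterStage("brain_mask", area_min=0.05, area_max=1.1,
                              aspect_max=1.5, major_max=1.2, dice_min=0.7,
                              dist_max=1.1),
    "eye": FilterStage("eye", area_min=0.5, area_max=1.2, aspect_max=1.5,
                       major_max=1.3, dice_min=0.9, dist_min=0.6,
                       dist_max=1.3, contrast_min=2.0),
}


def rasterize_ellipse(fit: EllipseFit, spacing, shape,
                      scale: float = 1.0) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the (scaled) ellipse."""
    sp = np.asarray(spacing, dtype=float)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    pts = np.stack([yy * sp[0] - fit.center[0], xx * sp[1] - fit.center[1]],
                   axis=-1)
    c, s = math.cos(fit.orientation), math.sin(fit.orientation)
    u = pts[..., 0] * c + pts[..., 1] * s
    v = -pts[..., 0] * s + pts[..., 1] * c
    sa, sb = scale * fit.a / 2.0, scale * fit.b / 2.0
    return (u / sa) ** 2 + (v / sb) ** 2 <= 1.0


def fit_ellipse(region: ExtremalRegion, spacing, shape=None) -> EllipseFit:
    """Fit the equal-moment ellipse to a region's pixel set.

    Moments are taken in mm (pixel indices scaled by the in-plane spacing),
    so axes scale linearly with voxel size. For a solid 2D ellipse the full
    axis length is 4 sqrt(eigenvalue) of the covariance of its points.
    """
    if region.area < 3:
        raise ValueError("ellipse fit requires at least 3 pixels")
    sp = np.asarray(spacing, dtype=float)
    pts = region.pixels * sp[np.newaxis, :]
    center = pts.mean(axis=0)
    cov_raw = np.cov((pts - center).T, bias=True)
    degenerate = bool(np.linalg.eigvalsh(cov_raw)[0] < 1e-12 * sp.min() ** 2)
    # discrete pixels carry finite extent; add the pixel's own variance
    cov = cov_raw + np.diag(sp ** 2) / 12.0
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    a = 4.0 * math.sqrt(evals[0])
    b = 4.0 * math.sqrt(evals[1])
    floor = float(sp.min())
    if degenerate or b < floor:
        b = floor  # collinear pixel sets: minor axis is one pixel wide
    orientation = math.atan2(evecs[1, 0], evecs[0, 0])
    area = math.pi * (a / 2.0) * (b / 2.0)
    if shape is None:
        shape = tuple(
            max(int(region.pixels[:, k].max()) + 1,
                int(math.ceil((center[k] + a / 2.0) / sp[k])) + 2)
            for k in (0, 1))
    emask = rasterize_ellipse(
        EllipseFit(center, a, b, orientation, area, 0.0), sp, shape)
    rmask = np.zeros(shape, dtype=bool)
    inb = (region.pixels[:, 0] < shape[0]) & (region.pixels[:, 1] < shape[1])
    rmask[region.pixels[inb, 0], region.pixels[inb, 1]] = True
    inter = np.count_nonzero(emask & rmask)
    denom = np.count_nonzero(emask) + np.count_nonzero(rmask)
    dice = 2.0 * inter / denom if denom else 0.0
    return EllipseFit(center, a, b, orientation, area, dice, degenerate)


class RibbonOutOfBounds(ValueError):
    """Ribbon around a region falls entirely outside the slice."""


def local_contrast(region: ExtremalRegion, slice_2d: np.ndarray, spacing,
                   fit: EllipseFit | None = None) -> float:
    """Median-intensity contrast of a region against its surrounding ribbon.

    The ribbon is the set difference between the fitted ellipse enlarged by
    50% in both axes and the ellipse itself, clipped to the slice. Returns
    median(inside) / median(ribbon); raises :class:`RibbonOutOfBounds` when
    the clipped ribbon is empty, which callers treat as a rejection.
    """
    slice_2d = np.asarray(slice_2d, dtype=float)
    fit = fit or fit_ellipse(region, spacing, slice_2d.shape)
    inner = rasterize_ellipse(fit, spacing, slice_2d.shape)
    outer = rasterize_ellipse(fit, spacing, slice_2d.shape, scale=1.5)
    ribbon = outer & ~inner
    if not ribbon.any() or not inner.any():
        raise RibbonOutOfBounds("contrast ribbon is empty at the slice edge")
    med_r = float(np.median(slice_2d[ribbon]))
    med_i = float(np.median(slice_2d[inner]))
    if med_r == 0:
        return math.inf if med_i > 0 else 1.0
    return med_i / med_r


def apply_filters(regions, stage: FilterStage, biometry, *,
                  brain_center: np.ndarray | None = None,
                  slices: dict | None = None, spacing=None,
                  fits: list | None = None) -> list:
    """Keep the regions satisfying every bound of one filter stage.

    Parameters
    ----------
    regions : list of ExtremalRegion
    stage : FilterStage
    biometry : (OFD, BPD, OD) in mm
    brain_center : world-mm point, required when the stage bounds the
        distance to the brain.
    slices : mapping slice_index -> 2D intensity grid; required when the
        stage bounds local contrast.
    spacing : in-plane spacing pair (mm); required if ``fits`` not given.
    fits : optional precomputed :class:`EllipseFit` per region.
    """
    ofd, bpd, od = biometry
    if stage.stage == "eye":
        a_ref, b_ref = od, od
    else:
        a_ref, b_ref = ofd, bpd
    ref_area = math.pi * (a_ref / 2.0) * (b_ref / 2.0)
    ref_aspect = a_ref / b_ref
    needs_dist = stage.dist_min is not None or stage.dist_max is not None
    if needs_dist and brain_center is None:
        raise ValueError(f"stage {stage.stage!r} requires a brain center")
    if stage.contrast_min is not None and slices is None:
        raise ValueError(f"stage {stage.stage!r} requires slice intensities")

    kept = []
    for i, region in enumerate(regions):
        fit = fits[i] if fits is not None else fit_ellipse(region, spacing)
        na = fit.area_mm2 / ref_area
        if stage.area_min is not None and na < stage.area_min:
            continue
        if stage.area_max is not None and na > stage.area_max:
            continue
        if (stage.aspect_max is not None
                and fit.aspect_ratio / ref_aspect > stage.aspect_max):
            continue
        if stage.major_max is not None and fit.a / a_ref > stage.major_max:
            continue
        if stage.dice_min is not None and fit.dice < stage.dice_min:
            continue
        if needs_dist:
            if region.barycenter_world is None:
                raise ValueError("region lacks a world barycenter")
            d = float(np.linalg.norm(
                np.asarray(region.barycenter_world) - np.asarray(brain_center)))
            nd = d / (ofd / 2.0)
            if stage.dist_min is not None and nd < stage.dist_min:
                continue
            if stage.dist_max is not None and nd > stage.dist_max:
                continue
        if stage.contrast_min is not None:
            try:
                c = local_contrast(region, slices[region.slice_index],
                                   spacing, fit=fit)
            except RibbonOutOfBounds:
                continue
            if c < stage.contrast_min:
                continue
        kept.append(region)
    return kept
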