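"""End-to-end head-pose detection for one scout volume.

Stages, in order: per-slice preparation and MSER detection over the full
field of view (global brain search), mean-shift clustering and fill-factor
ranking, mask regularization and brain centre, local exhaustive search in
the brain box, parabola-based slice pruning and 3D ellipsoid fit, eye
detection in the half-voxel-resampled box, pair selection by geometric
error, and anatomical-frame construction with left-right resolution and
the 30-degree tilt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import time

import numpy as np

from . import brainmask, eyes as eyes_mod, localize, pose as pose_mod
from .biometry import BiometryTable, load_biometry
from .config import PipelineConfig
from .mser import detect_msers
from .preproc import prepare_slice
from .regions import FILTER_STAGES, apply_filters, fit_ellipse
from .volume import VolumeGrid, resample_box

logger = logging.getLogger(__name__)

__all__ = ["DetectionResult", "detect_head_pose", "detect_regions_on_volume"]


@dataclass
class DetectionResult:
    """Landmarks, frame and diagnostics of one detection run."""

    b: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    frame: pose_mod.AnatomicalFrame
    transform: dict
    epsilon: float
    ambiguous: bool
    brain_mask: np.ndarray
    ellipsoid: brainmask.BrainEllipsoid
    diagnostics: dict = field(default_factory=dict)

    @property
    def labels(self) -> dict | None:
        return self.frame.labels

    def labeled_landmarks(self) -> dict:
        """{"b", "left", "right"}; ambiguous frames use the e1/e2 order."""
        if self.frame.labels is not None:
            return {"b": self.b, "left": self.frame.labels["left"],
                    "right": self.frame.labels["right"]}
        return {"b": self.b, "left": self.e1, "right": self.e2}

    def to_json_dict(self) -> dict:
        lm = self.labeled_landmarks()
        return {
            "B": list(map(float, self.b)),
            "E_left": list(map(float, lm["left"])),
            "E_right": list(map(float, lm["right"])),
            "LR": list(map(float, self.frame.lr)),
            "PA": list(map(float, self.frame.pa)),
            "IS": list(map(float, self.frame.is_)),
            "transform": [list(map(float, row))
                          for row in self.transform["transform"]],
            "ambiguous_flag": bool(self.ambiguous),
            "epsilon": float(self.epsilon),
            "diagnostics": self.diagnostics,
        }


def detect_regions_on_volume(vol: VolumeGrid, config: PipelineConfig,
                             stage_name: str, biometry_mm,
                             brain_center=None,
                             slice_range=None,
                             inplane_bounds=None):
    """Prepare slices, detect MSERs and filter them for one stage.

    ``slice_range`` restricts processing to ``range(lo, hi)`` slice indices;
    ``inplane_bounds`` is ((r0, r1), (c0, c1)) restricting each slice to a
    sub-window (partial-slice detection in the local box). Returns the kept
    regions with world barycenters, plus the raw-slice map used for the
    contrast filter.
    """
    stage = FILTER_STAGES[stage_name]
    sp2 = vol.inplane_spacing_pair()
    n_slices = vol.shape[vol.slice_axis]
    indices = range(n_slices) if slice_range is None \
        else range(max(slice_range[0], 0), min(slice_range[1], n_slices))
    raw_slices = {}
    kept_all = []
    for s in indices:
        raw = vol.get_slice(s)
        if inplane_bounds is not None:
            (r0, r1), (c0, c1) = inplane_bounds
            sub = raw[r0:r1, c0:c1]
            offset = np.array([r0, c0])
        else:
            sub = raw
            offset = np.array([0, 0])
        if sub.size == 0 or not sub.any():
            continue
        prep = prepare_slice(sub, sp2, config)
        regions = detect_msers(prep.product, config.mser)
        if not regions:
            continue
        raw_slices[s] = sub
        fits = []
        for r in regions:
            r.slice_index = s
            r.pixels = r.pixels  # in-window indices; offset applied below
            fits.append(fit_ellipse(r, sp2, sub.shape))
            vox = vol.slice_pixel_to_voxel(r.pixels + offset, s)
            r.barycenter_world = vol.voxels_to_world(vox).mean(axis=0)
        kept = apply_filters(regions, stage, biometry_mm,
                             brain_center=brain_center,
                             slices=raw_slices, spacing=sp2, fits=fits)
        for r in kept:
            r.pixels = r.pixels + offset
        kept_all.extend(kept)
    return kept_all


def _cluster_brain(vol: VolumeGrid, regions, ofd: float,
                   config: PipelineConfig):
    pts = np.array([r.barycenter_world for r in regions])
    lo, hi = vol.world_bounds()
    modes = localize.mean_shift_modes(
        pts, kernel_fwhm=config.f_clust_factor * ofd,
        grid_spacing=config.meanshift_grid_factor * ofd,
        tol=config.meanshift_tol_mm, max_iter=config.meanshift_max_iter,
        bounds=(lo, hi))
    clusters = localize.assign_members(regions, modes, ofd)
    for c in clusters:
        localize.build_cluster_mask(c, vol.shape, vol.slice_axis,
                                    vol.slice_pixel_to_voxel)
        localize.fill_factor(c)
    return clusters


def _box_bounds(vol: VolumeGrid, center_world, side: float):
    """Voxel-index bounds of the axis-aligned box around a world centre."""
    c = vol.world_to_voxels(center_world)[0]
    half = (side / 2.0) / vol.spacing
    lo = np.maximum(np.floor(c - half).astype(int), 0)
    hi = np.minimum(np.ceil(c + half).astype(int) + 1, np.array(vol.shape))
    return lo, hi


def detect_head_pose(vol: VolumeGrid, ga: float,
                     config: PipelineConfig | None = None,
                     biometry: BiometryTable | None = None
                     ) -> DetectionResult:
    """Run the full pipeline on one scout volume.

    Raises :class:`~fetalpose.localize.BrainNotFound` or
    :class:`~fetalpose.eyes.EyesNotFound` when a stage yields nothing.
    """
    config = config or PipelineConfig()
    biometry = biometry or load_biometry()
    bio = biometry.lookup(ga)
    ofd, bpd, od = bio
    diagnostics = {}
    t0 = time.perf_counter()

    # --- global brain search -------------------------------------------
    regions = detect_regions_on_volume(vol, config, "brain_localize", bio)
    diagnostics["n_regions_global"] = len(regions)
    logger.info("global stage: %d regions kept", len(regions))
    if not regions:
        raise localize.BrainNotFound("brain not found: no global regions")
    clusters = _cluster_brain(vol, regions, ofd, config)
    diagnostics["n_clusters"] = len(clusters)
    brain = localize.select_brain(clusters)
    mask = localize.regularize_slices(brain.mask, slice_axis=vol.slice_axis)
    b0 = localize.brain_center(mask, vol.voxels_to_world)
    diagnostics["t_global_s"] = round(time.perf_counter() - t0, 3)
    logger.info("brain located at %s (fill %.0f)", np.round(b0, 1),
                brain.fill)

    # --- local brain masking -------------------------------------------
    t1 = time.perf_counter()
    side = brainmask.search_box_side(ofd)
    lo_idx, hi_idx = _box_bounds(vol, b0, side)
    axes2 = vol.inplane_axes
    local_regions = detect_regions_on_volume(
        vol, config, "brain_mask", bio, brain_center=b0,
        slice_range=(lo_idx[vol.slice_axis], hi_idx[vol.slice_axis]),
        inplane_bounds=((lo_idx[axes2[0]], hi_idx[axes2[0]]),
                        (lo_idx[axes2[1]], hi_idx[axes2[1]])))
    diagnostics["n_regions_local"] = len(local_regions)
    mask = mask.copy()
    for r in local_regions:
        vox = vol.slice_pixel_to_voxel(r.pixels, r.slice_index).astype(int)
        mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    mask = brainmask.parabola_prune(
        mask, config.z_poly, slice_axis=vol.slice_axis,
        spacing=vol.inplane_spacing_pair())
    ellipsoid = brainmask.fit_ellipsoid(mask, vol.voxels_to_world)
    b = ellipsoid.center
    diagnostics["t_mask_s"] = round(time.perf_counter() - t1, 3)

    # --- eye detection --------------------------------------------------
    t2 = time.perf_counter()
    iso = vol.inplane_spacing / 2.0
    box = resample_box(vol, b, side, iso)
    eye_regions = detect_regions_on_volume(box, config, "eye", bio,
                                           brain_center=b)
    diagnostics["n_regions_eye"] = len(eye_regions)
    candidates = eyes_mod.cluster_candidates(eye_regions, od)
    diagnostics["n_eye_candidates"] = len(candidates)
    pair = eyes_mod.select_eyes(candidates, b, bio, lam=config.lam,
                                d_io=config.d_io_factor * od)
    diagnostics["t_eyes_s"] = round(time.perf_counter() - t2, 3)
    logger.info("eyes at %s / %s (eps %.3f)", np.round(pair.e1, 1),
                np.round(pair.e2, 1), pair.epsilon)

    # --- anatomical frame ----------------------------------------------
    frame = pose_mod.build_frame(b, pair.e1, pair.e2)
    frame = pose_mod.resolve_left_right(frame, ellipsoid, pair.e1, pair.e2, b)
    frame = pose_mod.apply_tilt(frame, config.theta_deg, sign=config.tilt_sign)
    transform = pose_mod.frame_to_transform(frame)
    diagnostics["t_total_s"] = round(time.perf_counter() - t0, 3)
    return DetectionResult(
        b=b, e1=pair.e1, e2=pair.e2, frame=frame, transform=transform,
        epsilon=pair.epsilon, ambiguous=frame.ambiguous, brain_mask=mask,
        ellipsoid=ellipsoid, diagnostics=diagnostics,
    )
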