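"""Anatomical frame construction from the brain centre and the two eyes.

The left-right axis runs through the eyes, the posterior-anterior axis from
the brain centre through the eye midpoint, and the inferior-superior axis
follows by perpendicularity; since motion can leave the first two axes
slightly non-perpendicular, LR is replaced by PA x IS to orthonormalize.
The eye plane sits roughly 30 deg below the brain's axial plane, so the
frame is tilted about LR by theta. The left-right sign is resolved from the
brain-mask ellipsoid: the plane containing its major axis and parallel to
LR splits the brain, and the inferior half is the one holding the eyes.

Output convention is RAS and right-handed: +LR points subject-left to
subject-right (so the eye on the +LR side is the anatomical *right* eye),
+PA posterior to anterior, +IS inferior to superior; det[LR PA IS] = +1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

import numpy as np

from .brainmask import BrainEllipsoid

__all__ = ["AnatomicalFrame", "CollinearLandmarks", "build_frame",
           "apply_tilt", "resolve_left_right", "frame_to_transform"]


class CollinearLandmarks(ValueError):
    """Brain centre and eyes are collinear; no frame can be built."""


@dataclass
class AnatomicalFrame:
    """Orthonormal LR/PA/IS axes with origin at the brain centre (mm)."""

    lr: np.ndarray
    pa: np.ndarray
    is_: np.ndarray
    origin: np.ndarray
    e1: np.ndarray | None = None
    e2: np.ndarray | None = None
    labels: dict | None = None       # {"left": point, "right": point}
    ambiguous: bool = False

    def rotation(self) -> np.ndarray:
        """Rows LR, PA, IS: world -> anatomical rotation matrix."""
        return np.stack([self.lr, self.pa, self.is_], axis=0)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise CollinearLandmarks("degenerate direction")
    return v / n


def build_frame(b, e1, e2) -> AnatomicalFrame:
    """Untilted, unlabeled frame from {B, E1, E2}.

    LR0 = (E2-E1)/||.||, PA = (mid(E1,E2)-B)/||.||, IS = LR0 x PA, and
    LR = PA x IS so the returned triad is exactly orthonormal even when the
    eye axis is not perpendicular to PA.
    """
    b, e1, e2 = (np.asarray(p, dtype=float) for p in (b, e1, e2))
    lr0 = _unit(e2 - e1)
    mid = 0.5 * (e1 + e2)
    pa = _unit(mid - b)
    cross = np.cross(lr0, pa)
    if np.linalg.norm(cross) < 1e-9:
        raise CollinearLandmarks("brain centre and eyes are collinear")
    is_ = _unit(cross)
    lr = np.cross(pa, is_)
    return AnatomicalFrame(lr=lr, pa=pa, is_=is_, origin=b, e1=e1, e2=e2)


def apply_tilt(frame: AnatomicalFrame, theta_deg: float,
               sign: int = 1) -> AnatomicalFrame:
    """Rotate PA and IS about LR by theta (degrees); LR is unchanged.

    The default sense moves IS away from the eyes' half-space (the eyes are
    inferior-anterior of the brain centre): with eyes along +PA of the
    untilted frame, PA' = cos(t) PA + sin(t) IS and IS' = cos(t) IS -
    sin(t) PA. ``sign=-1`` selects the opposite convention.
    """
    t = math.radians(theta_deg) * sign
    pa = math.cos(t) * frame.pa + math.sin(t) * frame.is_
    is_ = math.cos(t) * frame.is_ - math.sin(t) * frame.pa
    return replace(frame, pa=pa, is_=is_)


def resolve_left_right(frame: AnatomicalFrame, ellipsoid: BrainEllipsoid,
                       e1, e2, b,
                       min_angle_deg: float = 10.0,
                       min_anisotropy: float = 1.05) -> AnatomicalFrame:
    """Fix the LR sign from the brain ellipsoid; label the eyes.

    The plane H through the ellipsoid centre spanned by the major axis and
    LR divides the brain; the half-space containing the eye midpoint is
    inferior. If IS points into that half-space, LR and IS are negated
    together (preserving handedness). Degenerate geometry — a near-spherical
    mask, or a major axis within ``min_angle_deg`` of LR — leaves the frame
    unchanged with ``ambiguous=True``.
    """
    e1, e2, b = (np.asarray(p, dtype=float) for p in (e1, e2, b))
    a_dir = ellipsoid.major_axis
    cosang = abs(float(np.dot(a_dir, frame.lr)))
    angle = math.degrees(math.acos(np.clip(cosang, 0.0, 1.0)))
    if ellipsoid.isotropic or ellipsoid.anisotropy < min_anisotropy \
            or angle < min_angle_deg:
        return replace(frame, ambiguous=True, labels=None)
    normal = np.cross(a_dir, frame.lr)
    normal /= np.linalg.norm(normal)
    mid = 0.5 * (e1 + e2)
    side_eyes = float(np.dot(normal, mid - ellipsoid.center))
    side_is = float(np.dot(normal, frame.is_))
    lr, is_ = frame.lr, frame.is_
    if side_eyes * side_is > 0:  # IS points into the eyes' (inferior) half
        lr, is_ = -lr, -is_
    right = e1 if float(np.dot(e1 - mid, lr)) > 0 else e2
    left = e2 if right is e1 else e1
    return replace(frame, lr=lr, is_=is_, ambiguous=False,
                   labels={"left": left, "right": right})


def frame_to_transform(frame: AnatomicalFrame) -> dict:
    """4x4 world->anatomical rigid transform plus a prescription record.

    The rotation rows are LR, PA, IS and the translation -R B, so the brain
    centre maps to the anatomical origin. The prescription record carries
    the FOV centre and the three cardinal slice-stack normals.
    """
    r = frame.rotation()
    t = np.eye(4)
    t[:3, :3] = r
    t[:3, 3] = -r @ frame.origin
    return {
        "transform": t,
        "fov_center": frame.origin.copy(),
        "slice_normals": {
            "sagittal": frame.lr.copy(),
            "coronal": frame.pa.copy(),
            "axial": frame.is_.copy(),
        },
        "ambiguous": frame.ambiguous,
    }
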