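"""Validation metrics: success criterion, translation and rotation errors.

A detection is *successful* when each labeled eye barycenter lies within
1.2 x OD of its ground-truth landmark. Accuracy is summarized by the
Euclidean distances of the landmarks (translation error, mm) and by the
magnitude of the rotation aligning the detected triangle {B, E1, E2} to the
truth triangle (rotation error, degrees), obtained by centroid-subtracted
least-squares registration with a proper rotation enforced. Per-axis
rotation components use intrinsic x-y-z Euler angles of the recovered
rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = ["EvalResult", "success_criterion", "translation_error",
           "rotation_error", "evaluate_detection", "cohort_report"]


@dataclass
class EvalResult:
    success: bool
    success_agnostic: bool
    dt_b: float
    dt_e1: float
    dt_e2: float
    dr: float
    dt_axes: np.ndarray
    dr_axes: np.ndarray


def success_criterion(detected: dict, truth: dict, od: float,
                      rho: float = 1.2, label_agnostic: bool = False) -> bool:
    """Both labeled eyes within ``rho x OD`` (strict) of their landmarks.

    ``detected`` and ``truth`` map ``"left"``/``"right"`` to world-mm
    points. In label-agnostic mode the better of the two pairings counts.
    """
    dl = np.asarray(detected["left"], float)
    dr_ = np.asarray(detected["right"], float)
    tl = np.asarray(truth["left"], float)
    tr = np.asarray(truth["right"], float)
    lim = rho * od

    def ok(a, b, c, d):
        return (np.linalg.norm(a - b) < lim) and (np.linalg.norm(c - d) < lim)

    labeled = ok(dl, tl, dr_, tr)
    if not label_agnostic:
        return labeled
    return labeled or ok(dl, tr, dr_, tl)


def translation_error(detected: np.ndarray, truth: np.ndarray):
    """Euclidean distance (mm) and per-axis absolute components."""
    diff = np.asarray(detected, float) - np.asarray(truth, float)
    return float(np.linalg.norm(diff)), np.abs(diff)


def rotation_error(detected_points, truth_points):
    """Rotation magnitude (deg) between two landmark triangles.

    Both arguments are (3, 3) arrays of rows {B, E1, E2}; the optimal
    proper rotation comes from centroid-subtracted least squares (Kabsch).
    Returns ``(dR_deg, per_axis_deg)``.
    """
    a = np.asarray(detected_points, float)
    b = np.asarray(truth_points, float)
    if a.shape != (3, 3) or b.shape != (3, 3):
        raise ValueError("expected three 3D points per triangle")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    if min(np.linalg.norm(np.cross(ac[1] - ac[0], ac[2] - ac[0])),
           np.linalg.norm(np.cross(bc[1] - bc[0], bc[2] - bc[0]))) < 1e-9:
        raise ValueError("degenerate (collinear) landmark triangle")
    rot, _ = Rotation.align_vectors(bc, ac)
    dr = float(np.degrees(rot.magnitude()))
    per_axis = np.abs(rot.as_euler("XYZ", degrees=True))
    return dr, per_axis


def evaluate_detection(detected: dict, truth: dict, od: float,
                       rho: float = 1.2) -> EvalResult:
    """Full per-case evaluation from labeled landmark dictionaries.

    Each dict needs keys ``"b"``, ``"left"``, ``"right"`` (world mm).
    """
    dt_b, axes_b = translation_error(detected["b"], truth["b"])
    dt_e1, _ = translation_error(detected["left"], truth["left"])
    dt_e2, _ = translation_error(detected["right"], truth["right"])
    tri_d = np.stack([detected["b"], detected["left"], detected["right"]])
    tri_t = np.stack([truth["b"], truth["left"], truth["right"]])
    dr, dr_axes = rotation_error(tri_d, tri_t)
    return EvalResult(
        success=success_criterion(detected, truth, od, rho=rho),
        success_agnostic=success_criterion(detected, truth, od, rho=rho,
                                           label_agnostic=True),
        dt_b=dt_b, dt_e1=dt_e1, dt_e2=dt_e2, dr=dr,
        dt_axes=axes_b, dr_axes=dr_axes,
    )


def cohort_report(results: list) -> pd.DataFrame:
    """Min/Max/Mean/SD summary over a cohort of :class:`EvalResult`.

    Rotation statistics cover successful detections only (a failed pair of
    landmarks carries no meaningful orientation); translation and success
    rates cover every case. The first row carries the success rates.
    """
    if not results:
        raise ValueError("no results to report")
    succ = [r for r in results if r.success]
    cols = {
        "dT_B": [r.dt_b for r in results],
        "dT_E1": [r.dt_e1 for r in results],
        "dT_E2": [r.dt_e2 for r in results],
        "dR": [r.dr for r in succ],
    }
    for k, ax in enumerate("xyz"):
        cols[f"dt_{ax}"] = [r.dt_axes[k] for r in results]
        cols[f"dr_{ax}"] = [r.dr_axes[k] for r in succ]
    rows = ["Minimum", "Maximum", "Mean", "SD"]
    table = {}
    for name, vals in cols.items():
        v = np.asarray(vals, float)
        if len(v) == 0:
            table[name] = [np.nan] * 4
        else:
            table[name] = [v.min(), v.max(), v.mean(), v.std(ddof=0)]
    df = pd.DataFrame(table, index=rows)
    df.attrs["success_rate"] = float(np.mean([r.success for r in results]))
    df.attrs["success_rate_agnostic"] = float(
        np.mean([r.success_agnostic for r in results]))
    df.attrs["n"] = len(results)
    return df
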