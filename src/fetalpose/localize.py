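"""Global brain search: cross-slice clustering and mask regularization.

Filtered region barycenters are clustered in 3D world space by mean-shift
mode seeking with a Gaussian kernel of FWHM 0.5 x OFD. Each cluster carries
the union of its member pixel sets as a binary 3D mask; the brain is the
cluster whose mask is largest and most nearly ellipsoidal, ranked by the
fill factor F = |M and E| - |E \\ M| against the moment-fit ellipsoid E of
the mask. The winning mask is regularized slice-wise (hole fill, interior
empty-slice interpolation, protrusion removal) and its barycenter is the
brain centre B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preproc import FWHM_TO_SIGMA

__all__ = ["RegionCluster", "BrainNotFound", "mean_shift_modes",
           "assign_members", "fill_factor", "select_brain",
           "regularize_slices", "brain_center", "fit_ellipsoid_voxels"]

FILL_FACTOR_SENTINEL = -np.inf


class BrainNotFound(RuntimeError):
    """No candidate cluster survived the global brain search."""


@dataclass
class RegionCluster:
    """A 3D group of regions: converged mode, members and aggregate mask."""

    members: list
    centroid: np.ndarray
    mask: np.ndarray | None = None
    fill: float = FILL_FACTOR_SENTINEL

    @property
    def slice_support(self) -> int:
        return len({r.slice_index for r in self.members})

    def barycenter(self) -> np.ndarray:
        """Unweighted mean of member-region barycenters (world mm)."""
        return np.mean([r.barycenter_world for r in self.members], axis=0)


def mean_shift_modes(points: np.ndarray, kernel_fwhm: float,
                     grid_spacing: float | None = None, tol: float = 1.0,
                     max_iter: int = 100,
                     bounds: tuple | None = None) -> np.ndarray:
    """Gaussian mean-shift mode seeking from a regular grid of starts.

    Each start point P is iterated through the kernel-weighted mean of the
    input points until its displacement drops below ``tol`` (mm); converged
    points closer than ``10 x tol`` are merged. ``bounds`` is the (lo, hi)
    world box to cover with starting points; it defaults to the point cloud's
    bounding box. Returns an (m, 3) array of unique modes.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) == 0:
        return np.empty((0, 3))
    if grid_spacing is None:
        grid_spacing = kernel_fwhm
    sigma = kernel_fwhm * FWHM_TO_SIGMA
    lo, hi = bounds if bounds is not None else (points.min(0), points.max(0))
    axes = [np.arange(lo[k], hi[k] + grid_spacing, grid_spacing)
            for k in range(3)]
    starts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if len(starts) == 0:
        starts = points.mean(axis=0, keepdims=True)

    modes = []
    for p in starts:
        for _ in range(max_iter):
            w = np.exp(-0.5 * np.sum((points - p) ** 2, axis=1) / sigma ** 2)
            tot = w.sum()
            if tot < 1e-300:
                p = None
                break
            p_new = (w[:, None] * points).sum(axis=0) / tot
            if np.linalg.norm(p_new - p) < tol:
                p = p_new
                break
            p = p_new
        if p is None:
            continue
        for m in modes:
            if np.linalg.norm(m - p) < 10.0 * tol:
                break
        else:
            modes.append(p)
    return np.array(modes) if modes else np.empty((0, 3))


def assign_members(regions: list, modes: np.ndarray, ofd: float,
                   volume_shape=None) -> list:
    """Attach every region within 0.5 x OFD (strict) of a mode to its cluster.

    A region may join several clusters; clusters left without members are
    dropped. When ``volume_shape`` is given each cluster also aggregates the
    binary 3D mask of its member pixel sets (mask construction needs the
    members to know their slice placement, see the pipeline).
    """
    clusters = []
    radius = 0.5 * ofd
    for mode in np.atleast_2d(modes):
        members = [r for r in regions
                   if np.linalg.norm(np.asarray(r.barycenter_world) - mode)
                   < radius]
        if members:
            clusters.append(RegionCluster(members=members,
                                          centroid=np.asarray(mode)))
    return clusters


def build_cluster_mask(cluster: RegionCluster, volume_shape, slice_axis: int,
                       pixel_to_voxel) -> np.ndarray:
    """Union of member pixel sets as a binary 3D grid."""
    mask = np.zeros(volume_shape, dtype=bool)
    for r in cluster.members:
        vox = pixel_to_voxel(r.pixels, r.slice_index).astype(int)
        mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    cluster.mask = mask
    return mask


def fit_ellipsoid_voxels(mask: np.ndarray) -> np.ndarray | None:
    """Rasterize the moment-fit ellipsoid of a voxel mask (same grid).

    Returns a boolean grid of the voxels inside the ellipsoid, or ``None``
    for degenerate masks (< 4 voxels or coplanar). For a solid ellipsoid the
    full axis length is 2 sqrt(5 lambda) with lambda the covariance
    eigenvalues; no restriction on how close to spherical it is.
    """
    idx = np.argwhere(mask)
    if len(idx) < 4:
        return None
    center = idx.mean(axis=0)
    cov = np.cov((idx - center).T, bias=True) + np.eye(3) / 12.0
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals <= 0):
        return None
    semi = np.sqrt(5.0 * evals)
    out = np.zeros(mask.shape, dtype=bool)
    r = float(semi.max())
    lo = np.maximum(np.floor(center - r).astype(int), 0)
    hi = np.minimum(np.ceil(center + r).astype(int) + 1,
                    np.array(mask.shape))
    grid = np.stack(np.meshgrid(*[np.arange(lo[k], hi[k]) for k in range(3)],
                                indexing="ij"), axis=-1).astype(float)
    rel = (grid - center) @ evecs
    rho = np.sum((rel / semi) ** 2, axis=-1)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = rho <= 1.0
    return out


def fill_factor(cluster: RegionCluster) -> float:
    """F = |M and E| - |E \\ M| for the cluster mask M and its ellipsoid E."""
    mask = cluster.mask
    if mask is None or np.count_nonzero(mask) < 4:
        cluster.fill = FILL_FACTOR_SENTINEL
        return cluster.fill
    ell = fit_ellipsoid_voxels(mask)
    if ell is None:
        cluster.fill = FILL_FACTOR_SENTINEL
        return cluster.fill
    inter = np.count_nonzero(mask & ell)
    outside = np.count_nonzero(ell & ~mask)
    cluster.fill = float(inter - outside)
    return cluster.fill


def select_brain(clusters: list) -> RegionCluster:
    """Pick the cluster with the largest fill factor.

    Ties break deterministically on larger mask size, then smaller centroid
    z. Raises :class:`BrainNotFound` when no cluster is available.
    """
    if not clusters:
        raise BrainNotFound("brain not found: no region clusters")
    for c in clusters:
        if c.fill == FILL_FACTOR_SENTINEL and c.mask is not None:
            fill_factor(c)
    best = max(
        clusters,
        key=lambda c: (c.fill,
                       np.count_nonzero(c.mask) if c.mask is not None else 0,
                       -float(c.centroid[2])),
    )
    if best.fill == FILL_FACTOR_SENTINEL:
        raise BrainNotFound("brain not found: all clusters degenerate")
    return best


def _move_slice_axis(mask: np.ndarray, slice_axis: int) -> np.ndarray:
    return np.moveaxis(mask, slice_axis, 0)


def regularize_slices(mask: np.ndarray, slice_axis: int = 2) -> np.ndarray:
    """Slice-wise mask cleanup, applied once, in order:

    1. morphological hole fill within each slice;
    2. interior empty slices filled with the intersection of the nearest
       non-empty slice on each side (arbitrary gap widths);
    3. protrusion removal: a voxel is kept only if present on the nearest
       non-empty slice on at least one side.

    The three-step pass is repeated until the mask stops changing (almost
    always a single pass on anatomical masks), which makes the operation
    idempotent even on adversarial inputs where protrusion removal opens a
    new in-slice hole.
    """
    m = np.asarray(mask, dtype=bool)
    for _ in range(20):
        out = _regularize_once(m, slice_axis)
        if np.array_equal(out, m):
            return out
        m = out
    return m


def _regularize_once(mask: np.ndarray, slice_axis: int) -> np.ndarray:
    m = _move_slice_axis(np.asarray(mask, dtype=bool).copy(), slice_axis)
    n = m.shape[0]
    for s in range(n):
        if m[s].any():
            m[s] = ndimage.binary_fill_holes(m[s])
    nonempty = [s for s in range(n) if m[s].any()]
    if not nonempty:
        return np.moveaxis(m, 0, slice_axis)
    filled = m.copy()
    for s in range(nonempty[0] + 1, nonempty[-1]):
        if not m[s].any():
            below = max(i for i in nonempty if i < s)
            above = min(i for i in nonempty if i > s)
            filled[s] = m[below] & m[above]
    m = filled
    nonempty = [s for s in range(n) if m[s].any()]
    out = m.copy()
    for pos, s in enumerate(nonempty):
        below = m[nonempty[pos - 1]] if pos > 0 else None
        above = m[nonempty[pos + 1]] if pos < len(nonempty) - 1 else None
        keep = np.zeros_like(m[s])
        if below is not None:
            keep |= below
        if above is not None:
            keep |= above
        if below is None and above is None:
            keep[:] = True  # single-slice mask: nothing to compare against
        out[s] = m[s] & keep
    return np.moveaxis(out, 0, slice_axis)


def brain_center(mask: np.ndarray, voxels_to_world) -> np.ndarray:
    """Barycenter of the mask voxels in world mm (intensity-unweighted)."""
    idx = np.argwhere(mask)
    if len(idx) == 0:
        raise ValueError("brain_center of an empty mask")
    return voxels_to_world(idx).mean(axis=0)
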