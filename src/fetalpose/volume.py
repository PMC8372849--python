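"""Volume container and I/O.

All geometry in this package is evaluated in world millimetres: a voxel index
``(i, j, k)`` maps to the centre of the voxel through the affine, and every
anatomical threshold (diameters, distances, box sides) is applied in mm so
that anisotropic voxels never skew a comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates


class VolumeFormatError(ValueError):
    """Raised when a file cannot be interpreted as a 3D scalar volume."""


@dataclass
class VolumeGrid:
    """A 3D scalar image with voxel spacing and a voxel-to-world affine.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Scalar intensities in arbitrary units.
    spacing : ndarray, shape (3,)
        Per-axis voxel size in mm; strictly positive.
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm map (rigid + scale); must be invertible.
        A voxel's world position is the centre of the voxel.
    slice_axis : int
        Index of the acquisition-slice dimension (0, 1 or 2).
    """

    intensities: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray
    slice_axis: int = 2

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D volume, got {self.intensities.ndim}D"
            )
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if not np.all(self.spacing > 0):
            raise ValueError("voxel spacings must be strictly positive")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must be 0, 1 or 2")

    @property
    def shape(self) -> tuple:
        return self.intensities.shape

    @property
    def inplane_axes(self) -> tuple:
        return tuple(a for a in range(3) if a != self.slice_axis)

    @property
    def inplane_spacing(self) -> float:
        """Mean in-plane voxel size (mm)."""
        a, b = self.inplane_axes
        return float(0.5 * (self.spacing[a] + self.spacing[b]))

    def voxels_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world-mm points."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxels(self, xyz: np.ndarray) -> np.ndarray:
        """Map (N, 3) world-mm points to fractional voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_bounds(self) -> tuple:
        """(lo, hi) world coordinates of the voxel-centre bounding box."""
        shape = np.array(self.shape)
        corners = np.array(
            [[i * (shape[0] - 1), j * (shape[1] - 1), k * (shape[2] - 1)]
             for i in (0, 1) for j in (0, 1) for k in (0, 1)],
            dtype=float,
        )
        world = self.voxels_to_world(corners)
        return world.min(axis=0), world.max(axis=0)

    def get_slice(self, index: int) -> np.ndarray:
        """Return the 2D slice at the given index along ``slice_axis``."""
        return np.take(self.intensities, index, axis=self.slice_axis)

    def slice_pixel_to_voxel(self, pixels: np.ndarray, index: int) -> np.ndarray:
        """Lift (N, 2) in-slice pixel indices to (N, 3) voxel indices."""
        pixels = np.atleast_2d(pixels)
        out = np.empty((len(pixels), 3), dtype=float)
        a, b = self.inplane_axes
        out[:, a] = pixels[:, 0]
        out[:, b] = pixels[:, 1]
        out[:, self.slice_axis] = index
        return out

    def inplane_spacing_pair(self) -> np.ndarray:
        a, b = self.inplane_axes
        return self.spacing[[a, b]]


def read_volume(path, slice_axis: int | None = None) -> VolumeGrid:
    """Read a NIfTI-1/2 file into a :class:`VolumeGrid`.

    The slice axis is inferred as the axis with the largest voxel spacing;
    ties (e.g. isotropic volumes) default to axis 2. Pass ``slice_axis`` to
    override.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise VolumeFormatError(f"cannot read NIfTI volume {path!s}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path!s}: expected a 3D volume, got shape {data.shape}"
        )
    affine = np.asarray(img.affine, dtype=float)
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    if slice_axis is None:
        # largest-spacing axis; exact ties fall through to axis 2
        mx = spacing.max()
        candidates = np.flatnonzero(np.isclose(spacing, mx))
        slice_axis = 2 if 2 in candidates else int(candidates[0])
    return VolumeGrid(np.asarray(data, dtype=np.float64), spacing, affine,
                      slice_axis=int(slice_axis))


def write_volume(vol: VolumeGrid, path) -> None:
    """Write a :class:`VolumeGrid` (or binary mask) as NIfTI-1."""
    data = vol.intensities
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


def resample_box(vol: VolumeGrid, center: np.ndarray, side: float,
                 iso_spacing: float, fill_value: float = 0.0) -> VolumeGrid:
    """Trilinearly resample a cube of side ``side`` (mm) centred on ``center``.

    The cube is axis-aligned with the source volume's voxel axes and sampled
    on an isotropic grid of spacing ``iso_spacing``. Samples outside the
    source field of view take ``fill_value``. The returned grid keeps the
    source ``slice_axis`` so that per-slice processing stays aligned with the
    acquisition direction.
    """
    if side <= 0 or iso_spacing <= 0:
        raise ValueError("side and iso_spacing must be positive")
    center = np.asarray(center, dtype=float).reshape(3)
    lo, hi = vol.world_bounds()
    if np.any(center < lo) or np.any(center > hi):
        warnings.warn(
            "resample_box: center lies outside the volume bounding box; "
            "out-of-field samples take the fill value",
            stacklevel=2,
        )
    n = max(int(round(side / iso_spacing)), 1)
    # direction cosines of the source voxel axes
    dirs = vol.affine[:3, :3] / vol.spacing[np.newaxis, :]
    offsets = (np.arange(n) - (n - 1) / 2.0) * iso_spacing
    ii, jj, kk = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    pts = (center[np.newaxis, :]
           + np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) @ dirs.T)
    vox = vol.world_to_voxels(pts)
    sampled = map_coordinates(
        np.asarray(vol.intensities, dtype=np.float64), vox.T, order=1,
        mode="constant", cval=fill_value,
    ).reshape(n, n, n)
    origin = center + dirs @ (np.full(3, offsets[0]))
    affine = np.eye(4)
    affine[:3, :3] = dirs * iso_spacing
    affine[:3, 3] = origin
    return VolumeGrid(sampled, np.full(3, iso_spacing), affine,
                      slice_axis=vol.slice_axis)
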