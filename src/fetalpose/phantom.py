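"""Seeded synthetic scout generator with per-stage ground truth.

The phantom emulates a T2*-weighted EPI scout of the pregnant abdomen at
the scale the pose detector operates on: a bright ellipsoidal brain with
axes OFD x BPD x BPD for the gestational age, a darker ~3 mm skull shell,
two bright eye spheres of diameter OD placed anterior-inferior so that the
plane {B, E1, E2} is tilted ~30 deg from the brain's axial plane about LR,
a smooth maternal background texture at about half the brain intensity,
decoy bright blobs, additive Gaussian noise, a slow multiplicative shading
field (exercising the intensity flattening), and an optional in-plane
displacement between odd and even slices mimicking interleaved-acquisition
motion.

Tissue intensities (arbitrary units): brain 1.0, eyes 1.2, background 0.5,
skull shell 0.2, orbital rim 0.25. Default geometry: 240 x 240 x 180 mm
field of view at (3 mm)^2 in-plane and 3 mm slices (80 x 80 x 60 voxels,
60 slices — within the 30-90 slice range of the targeted acquisitions).
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from .biometry import BiometryTable, load_biometry
from .pose import AnatomicalFrame
from .volume import VolumeGrid

__all__ = ["PhantomSpec", "GroundTruth", "generate", "cohort", "INTENSITIES"]

INTENSITIES = {
    "brain": 1.0,
    "eye": 1.2,
    "background": 0.5,
    "skull": 0.2,
    "orbit_rim": 0.25,
}

SKULL_THICKNESS_MM = 3.0
ORBIT_RIM_MM = 3.0  # dark orbital bone/fat shell, same class as the skull
EYE_TILT_DEG = 30.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic scout."""

    ga: float = 31.0
    rotation_deg: tuple = (0.0, 0.0, 0.0)   # intrinsic x-y-z Euler angles
    translation_mm: tuple = (0.0, 0.0, 0.0)
    fov_mm: tuple = (240.0, 240.0, 180.0)
    in_plane_mm: float = 3.0
    slice_mm: float = 3.0
    noise_sigma: float = 0.05               # fraction of brain intensity
    odd_even_shift_mm: float = 1.0
    decoys: int = 3
    texture_amp: float = 0.3
    shading_amp: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not (self.in_plane_mm > 0 and self.slice_mm > 0):
            raise ValueError("spacings must be positive")
        if not (14.0 <= self.ga <= 40.0):
            raise ValueError("ga must lie in [14, 40] weeks")

    def pose_rotation(self) -> Rotation:
        return Rotation.from_euler("XYZ", self.rotation_deg, degrees=True)


@dataclass
class GroundTruth:
    """World-mm landmarks, true frame and true brain mask of a phantom."""

    b: np.ndarray
    e_left: np.ndarray
    e_right: np.ndarray
    frame: AnatomicalFrame
    brain_mask: np.ndarray
    biometry: tuple
    ga: float = 31.0


def _anatomy_geometry(ofd, bpd, od):
    """Eye centres and brain semi-axes in the local anatomical frame.

    Local axes: x = LR, y = PA, z = IS; origin at the brain centre. The
    brain-to-eye distance is OFD/2, the eye separation 2 x OD, and the eye
    midpoint direction is tilted 30 deg below the axial plane about LR.
    """
    semi = np.array([bpd / 2.0, ofd / 2.0, bpd / 2.0])
    t = math.radians(EYE_TILT_DEG)
    mid_dir = np.array([0.0, math.cos(t), -math.sin(t)])
    half_sep = od
    d_mid = math.sqrt((ofd / 2.0) ** 2 - half_sep ** 2)
    e_left = d_mid * mid_dir + np.array([-half_sep, 0.0, 0.0])
    e_right = d_mid * mid_dir + np.array([half_sep, 0.0, 0.0])
    return semi, e_left, e_right


def generate(spec: PhantomSpec,
             biometry: BiometryTable | None = None) -> tuple:
    """Render one phantom; deterministic given ``spec.seed``.

    Returns ``(VolumeGrid, GroundTruth)``.
    """
    biometry = biometry or load_biometry()
    ofd, bpd, od = biometry.lookup(spec.ga)
    rng = np.random.default_rng(spec.seed)

    shape = tuple(int(round(f / s)) for f, s in
                  zip(spec.fov_mm, (spec.in_plane_mm, spec.in_plane_mm,
                                    spec.slice_mm)))
    spacing = np.array([spec.in_plane_mm, spec.in_plane_mm, spec.slice_mm])
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = -spacing * (np.array(shape) - 1) / 2.0  # centred FOV

    rot = spec.pose_rotation()
    b_world = np.asarray(spec.translation_mm, dtype=float)
    semi, e_left_loc, e_right_loc = _anatomy_geometry(ofd, bpd, od)
    e_left = rot.apply(e_left_loc) + b_world
    e_right = rot.apply(e_right_loc) + b_world

    lo = affine[:3, 3]
    hi = lo + spacing * (np.array(shape) - 1)
    for name, p in (("brain centre", b_world), ("left eye", e_left),
                    ("right eye", e_right)):
        if np.any(p < lo + od) or np.any(p > hi - od):
            raise ValueError(f"{name} too close to the phantom FOV edge")

    # decoy blobs: bright spheres outside the head, some inside the
    # eye-search distance window so the pair selection is exercised
    decoy_centers, decoy_radii, decoy_vals = [], [], []
    guard = 0
    while len(decoy_centers) < spec.decoys and guard < 1000:
        guard += 1
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        dist = rng.uniform(0.7, 1.8) * (ofd / 2.0)
        c = b_world + rot.apply(u * dist)
        radius = rng.uniform(0.4, 1.0) * od
        if np.any(c < lo + radius) or np.any(c > hi - radius):
            continue
        rho_loc = (rot.inv().apply(c - b_world)) / (semi + SKULL_THICKNESS_MM
                                                    + radius)
        if np.sum(rho_loc ** 2) <= 1.0:
            continue  # overlaps the head
        if (np.linalg.norm(c - e_left) < 2 * od
                or np.linalg.norm(c - e_right) < 2 * od):
            continue
        decoy_centers.append(c)
        decoy_radii.append(radius)
        decoy_vals.append(rng.uniform(0.9, 1.15))

    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    world = (np.stack([ii, jj, kk], axis=-1) * spacing + lo).astype(float)

    # interleaved-acquisition motion: odd and even slices sample the anatomy
    # displaced by +/- shift/2 along a random in-plane direction
    if spec.odd_even_shift_mm > 0:
        ang = rng.uniform(0, 2 * np.pi)
        shift = np.array([math.cos(ang), math.sin(ang), 0.0]) \
            * spec.odd_even_shift_mm / 2.0
        sgn = np.where(kk % 2 == 0, 1.0, -1.0)[..., None]
        sample = world + sgn * shift[None, None, None, :]
    else:
        sample = world

    flat = sample.reshape(-1, 3)
    local = rot.inv().apply(flat - b_world)
    rho2 = np.sum((local / semi) ** 2, axis=1)
    shell_semi = semi + SKULL_THICKNESS_MM
    rho2_shell = np.sum((local / shell_semi) ** 2, axis=1)

    img = np.full(flat.shape[0], INTENSITIES["background"])
    tex = gaussian_filter(rng.standard_normal(shape), sigma=25.0 / spacing,
                          mode="mirror")
    tex /= max(np.abs(tex).max(), 1e-9)
    img += INTENSITIES["background"] * spec.texture_amp * tex.ravel()
    img[rho2_shell <= 1.0] = INTENSITIES["skull"]
    img[rho2 <= 1.0] = INTENSITIES["brain"]
    for c, radius, val in zip(decoy_centers, decoy_radii, decoy_vals):
        d = np.linalg.norm(flat - c, axis=1)
        img[d <= radius] = val
    for e in (e_left, e_right):
        d = np.linalg.norm(flat - e, axis=1)
        img[d <= od / 2.0 + ORBIT_RIM_MM] = INTENSITIES["orbit_rim"]
        img[d <= od / 2.0] = INTENSITIES["eye"]

    # slow multiplicative shading (coil-sensitivity surrogate)
    shade = gaussian_filter(rng.standard_normal(shape), sigma=60.0 / spacing,
                            mode="mirror")
    shade /= max(np.abs(shade).max(), 1e-9)
    img = img * (1.0 + spec.shading_amp * shade.ravel())

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma
                               * INTENSITIES["brain"], size=img.shape)

    vol = VolumeGrid(img.reshape(shape), spacing, affine, slice_axis=2)

    # ground truth evaluated on the undisplaced grid
    local_true = rot.inv().apply(world.reshape(-1, 3) - b_world)
    mask_true = (np.sum((local_true / semi) ** 2, axis=1) <= 1.0)\
        .reshape(shape)
    frame_true = AnatomicalFrame(
        lr=rot.apply([1.0, 0.0, 0.0]), pa=rot.apply([0.0, 1.0, 0.0]),
        is_=rot.apply([0.0, 0.0, 1.0]), origin=b_world,
        e1=e_left, e2=e_right,
        labels={"left": e_left, "right": e_right},
    )
    truth = GroundTruth(b=b_world, e_left=e_left, e_right=e_right,
                        frame=frame_true, brain_mask=mask_true,
                        biometry=(ofd, bpd, od), ga=spec.ga)
    return vol, truth


def cohort(n: int, ga_range=(26.0, 37.0), noise: float = 0.05,
           motion: float = 1.0, seed: int = 0, decoys: int = 3,
           biometry: BiometryTable | None = None):
    """Yield ``n`` phantoms with random poses; reproducible from ``seed``.

    Gestational ages are uniform over ``ga_range``, rotations uniform over
    SO(3) and translations jittered within +/- 15 mm per axis.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n)
    out = []
    for i in range(n):
        sub = int(child_seeds[i] % (2 ** 31 - 1))
        rng = np.random.default_rng(sub)
        rot = Rotation.random(rng=rng)
        spec = PhantomSpec(
            ga=float(rng.uniform(*ga_range)),
            rotation_deg=tuple(rot.as_euler("XYZ", degrees=True)),
            translation_mm=tuple(rng.uniform(-15.0, 15.0, size=3)),
            noise_sigma=noise,
            odd_even_shift_mm=motion,
            decoys=decoys,
            seed=sub,
        )
        out.append(generate(spec, biometry=biometry))
    return out
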