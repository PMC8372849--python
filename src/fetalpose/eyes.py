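"""Eye detection: candidate clustering and geometric pair selection.

The fetal eyes are searched inside the brain-centred box, resampled
isotropically at half the in-plane voxel size to help detect the small
spheres. Filtered regions (stage C, including local contrast >= 2 and a
distance window around the brain) are grouped into candidate clusters by a
radius of 0.75 x OD; the pair of clusters best matching the expected
brain-eye geometry minimizes

    eps(j,k) = |(u_j + u_k)/OFD - 1|                (brain-eye distance prior)
             + 2 lambda |u_j - u_k| / (u_j + u_k)   (left/right symmetry)
             + |w / d_io - 1|                       (eye separation prior)
             + |(s_j + s_k)/(2 s_max) - 1|          (multi-slice support)

with u the brain-to-cluster distances, w the inter-cluster distance, s the
slice supports and d_io the expected eye separation (default 2 x OD; the
published equation loses this constant to typography, so it is explicitly
configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .localize import RegionCluster

__all__ = ["EyePair", "EyesNotFound", "cluster_candidates", "pair_error",
           "select_eyes"]


class EyesNotFound(RuntimeError):
    """Fewer than two eye candidates survived detection."""


@dataclass
class EyePair:
    """The selected pair of eye-cluster barycenters (world mm)."""

    e1: np.ndarray
    e2: np.ndarray
    epsilon: float
    s1: int = 0
    s2: int = 0
    terms: tuple = ()


def cluster_candidates(regions: list, od: float) -> list:
    """Seed one candidate per region: itself plus all others within 0.75 OD.

    Candidates with identical member sets are merged, which typically leaves
    on the order of 10-20 unique clusters. Raises :class:`EyesNotFound` when
    no region is available.
    """
    if not regions:
        raise EyesNotFound("eyes not found: no candidate regions")
    radius = 0.75 * od
    pts = np.array([r.barycenter_world for r in regions], dtype=float)
    seen = {}
    for i in range(len(regions)):
        d = np.linalg.norm(pts - pts[i], axis=1)
        members = tuple(np.flatnonzero(d < radius).tolist())
        if members not in seen:
            cluster = RegionCluster(
                members=[regions[m] for m in members],
                centroid=pts[list(members)].mean(axis=0),
            )
            seen[members] = cluster
    return list(seen.values())


def pair_error(j: RegionCluster, k: RegionCluster, brain_center, ofd: float,
               od: float, lam: float = 4.0, d_io: float | None = None,
               s_max: int | None = None) -> float:
    """Deviation of a candidate pair from the expected brain-eye geometry."""
    if d_io is None:
        d_io = 2.0 * od
    b = np.asarray(brain_center, dtype=float)
    mj, mk = j.barycenter(), k.barycenter()
    u_j = float(np.linalg.norm(mj - b))
    u_k = float(np.linalg.norm(mk - b))
    w = float(np.linalg.norm(mj - mk))
    if w < 1e-9:
        return float("inf")
    if s_max is None:
        s_max = max(j.slice_support, k.slice_support)
    t1 = abs((u_j + u_k) / ofd - 1.0)
    t2 = 2.0 * lam * abs(u_j - u_k) / (u_j + u_k)
    t3 = abs(w / d_io - 1.0)
    t4 = abs((j.slice_support + k.slice_support) / (2.0 * s_max) - 1.0)
    return t1 + t2 + t3 + t4


def select_eyes(candidates: list, brain_center, biometry, lam: float = 4.0,
                d_io: float | None = None) -> EyePair:
    """Exhaustive scan over unordered candidate pairs; minimal-eps wins.

    Ties break on the lexicographic order of the pair's barycenters.
    """
    if len(candidates) < 2:
        raise EyesNotFound(
            f"eyes not found: {len(candidates)} candidate cluster(s)")
    ofd, _, od = biometry
    s_max = max(c.slice_support for c in candidates)
    best = None
    for j, k in combinations(candidates, 2):
        eps = pair_error(j, k, brain_center, ofd, od, lam=lam, d_io=d_io,
                         s_max=s_max)
        bj, bk = j.barycenter(), k.barycenter()
        lex = tuple(np.minimum(bj, bk)) + tuple(np.maximum(bj, bk))
        key = (eps, lex)
        if best is None or key < best[0]:
            best = (key, j, k, eps)
    _, j, k, eps = best
    return EyePair(e1=j.barycenter(), e2=k.barycenter(), epsilon=float(eps),
                   s1=j.slice_support, s2=k.slice_support)
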