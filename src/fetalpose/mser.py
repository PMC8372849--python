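"""Maximally stable extremal regions on 2D slices.

An extremal region is a connected component of an upper level set
U_t = {p : I(p) >= t} (bright polarity: brain, CSF and eyes are brighter
than the surrounding tissue in T2*-weighted EPI). Tracking a component while
the threshold descends, its pixel set grows; a *maximally stable* region is
a component whose relative growth rate

    q(C) = (|A(C, t_hi - delta)| - |C|) / |C|

is a local minimum over the component tree, where t_hi is the highest
threshold at which the set C appears, A(C, tau) is the component of U_tau
containing C, and delta is the stability step on the quantized intensity
scale. The exact rules, shared by :func:`detect_msers` and the brute-force
:func:`mser_oracle`:

* intensities are quantized to ``n_levels`` levels (integer inputs already in
  range are taken as-is);
* atoms are the distinct components of all upper level sets, 4-connected;
* a component is a candidate iff its area lies in ``[min_area, max_area]``,
  ``q < max_variation``, ``q`` is strictly below its parent's and not above
  any child's, and it is not the full-image root;
* nested near-duplicates (relative area difference below ``min_diversity``)
  are suppressed greedily, keeping the most stable region.

``detect_msers`` runs on the max-tree (union-find component tree);
``mser_oracle`` thresholds exhaustively at every level and labels components
independently — the two must agree exactly, which the test suite checks on
randomized images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import max_tree

from .config import MserParams

__all__ = ["ExtremalRegion", "detect_msers", "mser_oracle", "quantize_slice"]


@dataclass
class ExtremalRegion:
    """One MSER: pixel set on one slice plus summary descriptors.

    ``pixels`` is an (N, 2) integer array of in-slice indices, a single
    4-connected component. ``level`` is the quantized threshold at which the
    set first appears, ``stability`` its growth score q (lower is more
    stable). ``barycenter_world`` (mm) is filled in by the pipeline once the
    slice is placed in the volume.
    """

    pixels: np.ndarray
    slice_index: int = -1
    level: int = 0
    stability: float = 0.0
    barycenter_world: np.ndarray | None = None

    @property
    def area(self) -> int:
        return len(self.pixels)

    def barycenter_pixels(self) -> np.ndarray:
        return self.pixels.mean(axis=0)


def quantize_slice(slice_2d: np.ndarray, n_levels: int = 256) -> np.ndarray:
    """Quantize a slice to integer levels ``0 .. n_levels-1``.

    Integer-valued inputs already within range are passed through unchanged
    (so constructed integer test images keep their levels); anything else is
    rescaled linearly. A constant slice maps to all zeros.
    """
    a = np.asarray(slice_2d)
    if np.issubdtype(a.dtype, np.integer):
        if a.size and a.min() >= 0 and a.max() < n_levels:
            return a.astype(np.int64)
        a = a.astype(np.float64)
    a = np.asarray(a, dtype=np.float64)
    lo, hi = float(a.min()), float(a.max())
    if hi - lo < 1e-300:
        return np.zeros(a.shape, dtype=np.int64)
    return np.rint((a - lo) / (hi - lo) * (n_levels - 1)).astype(np.int64)


def _select_candidates(nodes, params: MserParams, total_px: int):
    """Apply the shared candidate + diversity rules.

    ``nodes`` maps node id -> dict with keys area, q, parent, children,
    t_hi, min_pixel, is_root, nested(a, b) handled by caller via the
    ``contains`` callable stored under key "contains".
    """
    # local-minimum + bounds
    max_area = int(round(params.max_area_frac * total_px))
    cand = []
    for nid, nd in nodes.items():
        if nd["is_root"]:
            continue
        if not (params.min_area <= nd["area"] <= max_area):
            continue
        if not (nd["q"] < params.max_variation):
            continue
        pq = nodes[nd["parent"]]["q"] if nd["parent"] is not None else np.inf
        if not (nd["q"] < pq):
            continue
        if any(nd["q"] > nodes[c]["q"] for c in nd["children"]):
            continue
        cand.append(nid)
    # greedy min-diversity suppression, most stable first
    cand.sort(key=lambda nid: (nodes[nid]["q"], nodes[nid]["area"],
                               -nodes[nid]["t_hi"], nodes[nid]["min_pixel"]))
    accepted = []
    for nid in cand:
        nd = nodes[nid]
        ok = True
        for aid in accepted:
            ad = nodes[aid]
            if nd["contains"](aid, nid) or nd["contains"](nid, aid):
                big, small = max(nd["area"], ad["area"]), min(nd["area"], ad["area"])
                if (big - small) / big < params.min_diversity:
                    ok = False
                    break
        if ok:
            accepted.append(nid)
    return accepted


def detect_msers(slice_2d: np.ndarray,
                 params: MserParams | None = None) -> list[ExtremalRegion]:
    """Detect bright-polarity MSERs on one slice via the max-tree."""
    params = params or MserParams()
    a = np.asarray(slice_2d)
    if a.ndim != 2:
        raise ValueError(f"detect_msers expects a 2D slice, got {a.ndim}D")
    if not np.all(np.isfinite(a)):
        raise ValueError("slice contains non-finite values")
    L = quantize_slice(a, params.n_levels)
    total = L.size
    if total == 0 or L.min() == L.max():
        return []
    flat = L.ravel()
    parent, order = max_tree(L, connectivity=1)
    parent = parent.ravel()
    root = order[0]

    # canonical pixel of each node: value differs from parent's (or root)
    canonical_mask = flat[parent] != flat
    canonical_mask[root] = True
    canon = np.where(canonical_mask, np.arange(total), parent)
    canon_ids = np.flatnonzero(canonical_mask)

    # own-pixel counts, then subtree areas / min pixel ids accumulated from
    # high to low values (parents always have strictly lower values)
    area = np.bincount(canon, minlength=total).astype(np.int64)
    min_pixel = np.full(total, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(min_pixel, canon, np.arange(total))
    vals = flat[canon_ids]
    for v in np.unique(vals)[::-1]:
        sel = canon_ids[(vals == v) & (canon_ids != root)]
        if len(sel):
            np.add.at(area, parent[sel], area[sel])
            np.minimum.at(min_pixel, parent[sel], min_pixel[sel])

    # per-node stability q: area of the containing component delta levels
    # below the node's birth level, relative to the node's own area
    q = np.empty(len(canon_ids))
    for k, c in enumerate(canon_ids):
        if c == root:
            q[k] = np.inf
            continue
        tau = flat[c] - params.delta
        a_node = c
        while a_node != root and flat[parent[a_node]] >= tau:
            a_node = parent[a_node]
        q[k] = (area[a_node] - area[c]) / area[c]

    # children lists and Euler tour for subtree extraction / nesting tests
    children: dict[int, list[int]] = {int(c): [] for c in canon_ids}
    for c in canon_ids:
        if c != root:
            children[int(parent[c])].append(int(c))
    tin = {}
    tout = {}
    t = 0
    stack = [(int(root), False)]
    while stack:
        node, done = stack.pop()
        if done:
            tout[node] = t
            continue
        tin[node] = t
        t += 1
        stack.append((node, True))
        for ch in children[node]:
            stack.append((ch, False))

    def contains(outer: int, inner: int) -> bool:
        return tin[outer] <= tin[inner] < tout[outer] and outer != inner

    nodes = {}
    for k, c in enumerate(canon_ids):
        c = int(c)
        nodes[c] = {
            "area": int(area[c]),
            "q": float(q[k]),
            "parent": None if c == root else int(parent[c]),
            "children": children[c],
            "t_hi": int(flat[c]),
            "min_pixel": int(min_pixel[c]),
            "is_root": c == root,
            "contains": contains,
        }
    accepted = _select_candidates(nodes, params, total)

    # gather pixel sets: sort pixels by the tour index of their canonical node
    pix_tin = np.array([tin[int(c)] for c in canon], dtype=np.int64)
    order_px = np.argsort(pix_tin, kind="stable")
    sorted_tin = pix_tin[order_px]
    w = L.shape[1]
    regions = []
    for nid in accepted:
        lo = np.searchsorted(sorted_tin, tin[nid], side="left")
        hi = np.searchsorted(sorted_tin, tout[nid], side="left")
        flat_px = order_px[lo:hi]
        pix = np.stack([flat_px // w, flat_px % w], axis=1)
        pix = pix[np.lexsort((pix[:, 1], pix[:, 0]))]
        regions.append(ExtremalRegion(pixels=pix, level=nodes[nid]["t_hi"],
                                      stability=nodes[nid]["q"]))
    regions.sort(key=lambda r: (r.area, r.level,
                                int(r.pixels[0, 0] * w + r.pixels[0, 1])))
    return regions


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def mser_oracle(slice_2d: np.ndarray,
                params: MserParams | None = None) -> list[ExtremalRegion]:
    """Brute-force MSER reference: exhaustive thresholding at every level.

    Semantics are identical to :func:`detect_msers` by construction, but the
    component tree is assembled by labelling every upper level set with
    ``scipy.ndimage.label`` and matching identical pixel sets across levels.
    Restricted to small quantized images (<= 48 x 48, <= 64 distinct levels).
    """
    params = params or MserParams()
    a = np.asarray(slice_2d)
    if a.ndim != 2:
        raise ValueError("oracle expects a 2D slice")
    if a.shape[0] > 48 or a.shape[1] > 48:
        raise ValueError("oracle capped at 48x48 images")
    L = quantize_slice(a, params.n_levels)
    if len(np.unique(L)) > 64:
        raise ValueError("oracle capped at 64 quantized levels")
    total = L.size
    if total == 0 or L.min() == L.max():
        return []
    w = L.shape[1]
    lo_level, hi_level = int(L.min()), int(L.max())

    # all distinct components with their level intervals
    comp_interval: dict[frozenset, list] = {}  # set -> [t_lo, t_hi]
    comps_at_level: dict[int, list[frozenset]] = {}
    for t in range(hi_level, lo_level - 1, -1):
        lab, n = ndimage.label(L >= t, structure=_CROSS)
        sets = []
        flat_lab = lab.ravel()
        for cid in range(1, n + 1):
            s = frozenset(np.flatnonzero(flat_lab == cid).tolist())
            sets.append(s)
            if s in comp_interval:
                comp_interval[s][0] = t
            else:
                comp_interval[s] = [t, t]
        comps_at_level[t] = sets
    all_sets = list(comp_interval)
    root_set = frozenset(range(total))  # U at the minimum level

    def containing_at(pixels: frozenset, tau: int) -> frozenset:
        if tau <= lo_level:
            return root_set
        rep = next(iter(pixels))
        for s in comps_at_level[tau]:
            if rep in s:
                return s
        raise AssertionError("component vanished above its own level")

    ids = {s: i for i, s in enumerate(all_sets)}
    nodes = {}
    for s in all_sets:
        t_lo, t_hi = comp_interval[s]
        parent_set = None if s == root_set else containing_at(s, t_lo - 1)
        tau = t_hi - params.delta
        grown = len(containing_at(s, tau)) if tau > lo_level else total
        if tau >= t_lo:
            grown = len(s)
        qv = (grown - len(s)) / len(s) if s != root_set else np.inf
        nodes[ids[s]] = {
            "area": len(s),
            "q": qv,
            "parent": None if parent_set is None else ids[parent_set],
            "children": [],
            "t_hi": t_hi,
            "min_pixel": min(s),
            "is_root": s == root_set,
            "pixels": s,
        }
    for i, nd in nodes.items():
        if nd["parent"] is not None:
            nodes[nd["parent"]]["children"].append(i)

    def contains(outer: int, inner: int) -> bool:
        return outer != inner and nodes[inner]["pixels"] < nodes[outer]["pixels"]

    for nd in nodes.values():
        nd["contains"] = contains

    accepted = _select_candidates(nodes, params, total)
    regions = []
    for nid in accepted:
        nd = nodes[nid]
        flat_px = np.array(sorted(nd["pixels"]), dtype=np.int64)
        pix = np.stack([flat_px // w, flat_px % w], axis=1)
        regions.append(ExtremalRegion(pixels=pix, level=nd["t_hi"],
                                      stability=float(nd["q"])))
    regions.sort(key=lambda r: (r.area, r.level,
                                int(r.pixels[0, 0] * w + r.pixels[0, 1])))
    return regions
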