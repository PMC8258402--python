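"""From delineation mask to ordered centerline.

Mirrors the measurement chain used for perforating-artery morphometry
on thin-slab minimum-intensity projections: project (if 3D), thin the
binary delineation to a one-pixel skeleton, prune false spurs, then
walk the longest geodesic path between skeleton endpoints.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from skimage.morphology import skeletonize as _sk_skeletonize

from .types import Centerline, DisconnectedSkeletonError, VesselMask

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)]


def min_intensity_projection(
    volume: np.ndarray,
    spacing: tuple[float, float, float],
    axis: int,
    slab_mm: float,
    slab_center_mm: float,
) -> np.ndarray:
    """Thin-slab minimum intensity projection.

    The slab spans ``slab_center_mm ± slab_mm / 2`` along ``axis``
    (voxel centres at ``index * spacing[axis]``).  Slab boundaries are
    resolved to whole voxels with ties rounded toward the slab centre.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"volume must be 3D, got {volume.ndim}D")
    if not 0 <= axis < 3:
        raise ValueError(f"axis must be 0..2, got {axis}")
    if slab_mm <= 0:
        raise ValueError("slab thickness must be positive")
    sp = spacing[axis]
    lo = (slab_center_mm - slab_mm / 2) / sp
    hi = (slab_center_mm + slab_mm / 2) / sp
    ilo = int(np.floor(lo + 0.5))       # ties round up, toward the centre
    ihi = int(np.ceil(hi - 0.5))        # ties round down, toward the centre
    n = volume.shape[axis]
    if ihi < 0 or ilo > n - 1:
        raise ValueError("slab lies entirely outside the volume")
    ilo, ihi = max(ilo, 0), min(ihi, n - 1)
    index = [slice(None)] * 3
    index[axis] = slice(ilo, ihi + 1)
    return np.min(volume[tuple(index)], axis=axis)


def skeletonize(mask: VesselMask) -> VesselMask:
    """One-pixel-wide 8-connected medial skeleton of the delineation."""
    skel = _sk_skeletonize(mask.raster)
    if not skel.any():
        raise ValueError("skeletonization removed all foreground")
    return VesselMask(skel, mask.spacing, mask.origin)


def _pixel_graph(mask: VesselMask) -> nx.Graph:
    """8-connectivity graph over foreground pixels, edge weights in mm."""
    rows, cols = np.nonzero(mask.raster)
    fg = set(zip(rows.tolist(), cols.tolist()))
    g = nx.Graph()
    g.add_nodes_from(fg)
    row_mm, col_mm = mask.spacing
    for r, c in fg:
        for dr, dc in _NEIGHBORS:
            nb = (r + dr, c + dc)
            if nb in fg and not g.has_edge((r, c), nb):
                w = float(np.hypot(dr * row_mm, dc * col_mm))
                g.add_edge((r, c), nb, weight=w)
    return g


def _longest_geodesic(g: nx.Graph) -> tuple[float, list[tuple[int, int]]]:
    """Longest shortest-path between degree-1 nodes; ties resolved by the
    lexicographically smallest (row, col) start pixel."""
    endpoints = sorted(n for n in g.nodes if g.degree(n) == 1)
    if len(g) == 1:
        raise ValueError("skeleton has a single pixel; no path to extract")
    if not endpoints:
        raise ValueError("skeleton has no endpoints (closed loop?)")
    best: tuple[float, list] | None = None
    for src in endpoints:
        dist, paths = nx.single_source_dijkstra(g, src, weight="weight")
        for dst in endpoints:
            if dst == src:
                continue
            d = dist.get(dst)
            if d is None:
                continue
            path = paths[dst]
            start = min(path[0], path[-1])
            if path[0] != start:
                path = path[::-1]
            cand = (d, path)
            if best is None or d > best[0] + 1e-12 or (
                abs(d - best[0]) <= 1e-12 and path[0] < best[1][0]
            ):
                best = cand
    assert best is not None
    return best


def prune_spurs(skeleton: VesselMask, min_branch_mm: float = 2.0) -> VesselMask:
    """Iteratively remove terminal branches shorter than ``min_branch_mm``.

    Only side branches hanging off a junction are candidates; pixels on
    the longest geodesic path are never removed, so the main vessel
    course survives even aggressive thresholds.  Stable under repeated
    application.
    """
    if min_branch_mm < 0:
        raise ValueError("min_branch_mm must be non-negative")
    raster = skeleton.raster.copy()
    while True:
        mask = VesselMask(raster, skeleton.spacing, skeleton.origin)
        g = _pixel_graph(mask)
        n_comp = nx.number_connected_components(g)
        if n_comp != 1:
            raise DisconnectedSkeletonError(n_comp)
        if len(g) == 1:
            break
        try:
            _, main_path = _longest_geodesic(g)
        except ValueError:
            break                       # loop with no endpoints: nothing to prune
        protected = set(main_path)
        removed_any = False
        for ep in [n for n in g.nodes if g.degree(n) == 1]:
            if ep in protected:
                continue
            # walk from the endpoint until the branch anchors on the
            # main path or on a junction of other branches
            branch = [ep]
            length = 0.0
            cur = ep
            anchored = False
            while True:
                nxt = [n for n in g.neighbors(cur) if n not in branch]
                if not nxt:
                    break
                step = min(nxt)
                length += g.edges[cur, step]["weight"]
                if step in protected or g.degree(step) >= 3:
                    anchored = True
                    break
                branch.append(step)
                cur = step
            if anchored and length < min_branch_mm:
                for r, c in branch:
                    raster[r, c] = False
                removed_any = True
        if not removed_any:
            break
        # removing a spur can leave a redundant bump where it attached
        # (a pixel kept 8-connected through diagonals); re-thinning
        # clears it without touching one-pixel-wide stretches
        raster = _sk_skeletonize(raster)
    if not raster.any():
        raise ValueError("pruning removed the entire skeleton; "
                         "min_branch_mm too large")
    return VesselMask(raster, skeleton.spacing, skeleton.origin)


def extract_path(skeleton: VesselMask) -> Centerline:
    """Ordered centerline along the longest endpoint-to-endpoint geodesic.

    Raises :class:`DisconnectedSkeletonError` (with the component count)
    when the skeleton is not a single connected component.
    """
    g = _pixel_graph(skeleton)
    n_comp = nx.number_connected_components(g)
    if n_comp != 1:
        raise DisconnectedSkeletonError(n_comp)
    _, path = _longest_geodesic(g)
    rows = np.array([p[0] for p in path])
    cols = np.array([p[1] for p in path])
    points = skeleton.pixel_to_physical(rows, cols)
    return Centerline(points, source_spacing=skeleton.spacing)


def smooth_centerline(c: Centerline, window: int = 5) -> Centerline:
    """Moving-average smoothing of a pixel-chain centerline.

    Summing steps along a digitized 8-connected chain overestimates the
    true curve length by up to ~8% (staircase bias); a symmetric moving
    average removes most of it.  The window shrinks near the ends
    (``w_i = min(window, i, n-1-i)``) so the averaging stays symmetric
    and the two endpoints are preserved exactly.  ``window=1`` (a 3-point
    average) already reduces the length bias to ~1% on smooth vessels;
    larger windows start to shorten genuinely curved sections.
    """
    if window < 1:
        return c
    pts = c.points
    n = len(pts)
    out = np.empty_like(pts)
    for i in range(n):
        w = min(window, i, n - 1 - i)
        out[i] = pts[i - w:i + w + 1].mean(axis=0)
    keep = np.ones(n, dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(out, axis=0), axis=1) > 1e-12
    return Centerline(out[keep], c.source_spacing)


def mask_to_centerline(
    mask: VesselMask, min_branch_mm: float = 2.0, smooth_window: int = 1,
) -> Centerline:
    """Convenience chain: skeletonize -> prune spurs -> extract path ->
    smooth the pixel chain."""
    path = extract_path(prune_spurs(skeletonize(mask), min_branch_mm))
    return smooth_centerline(path, smooth_window)
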