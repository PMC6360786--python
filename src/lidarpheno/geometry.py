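"""Planar-surface geometry: triangle areas and clipping by height slabs.

Ground-truth per-layer areas are computed analytically by clipping each
surface triangle against horizontal planes (Sutherland-Hodgman in 3D)
and summing exact polygon areas.
"""

from __future__ import annotations

import numpy as np


def triangle_area(tri: np.ndarray) -> float:
    """One-sided area of a 3D triangle (3, 3)."""
    a, b, c = np.asarray(tri, dtype=float)
    return 0.5 * float(np.linalg.norm(np.cross(b - a, c - a)))


def polygon_area_3d(pts: np.ndarray) -> float:
    """Area of a planar 3D polygon given as an ordered vertex ring."""
    pts = np.asarray(pts, dtype=float)
    if len(pts) < 3:
        return 0.0
    v = pts[1:] - pts[0]
    cross = np.cross(v[:-1], v[1:])
    return 0.5 * float(np.linalg.norm(cross.sum(axis=0)))


def clip_polygon_z(pts: np.ndarray, z0: float, keep_above: bool) -> np.ndarray:
    """Clip a planar polygon against the halfspace z >= z0 (or z <= z0)."""
    pts = np.asarray(pts, dtype=float)
    out: list[np.ndarray] = []
    n = len(pts)
    for i in range(n):
        cur, nxt = pts[i], pts[(i + 1) % n]
        cin = (cur[2] >= z0) if keep_above else (cur[2] <= z0)
        nin = (nxt[2] >= z0) if keep_above else (nxt[2] <= z0)
        if cin:
            out.append(cur)
        if cin != nin:
            t = (z0 - cur[2]) / (nxt[2] - cur[2])
            out.append(cur + t * (nxt - cur))
    return np.array(out) if out else np.empty((0, 3))


def areas_per_slab(triangles: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Sum of one-sided triangle areas falling in each z slab.

    Slabs are half-open [edges[k], edges[k+1]); geometry exactly on a
    shared boundary contributes zero area either way, so the clipped
    areas sum to the total triangle area.
    """
    triangles = np.asarray(triangles, dtype=float)
    edges = np.asarray(edges, dtype=float)
    n_slabs = len(edges) - 1
    areas = np.zeros(n_slabs)
    for tri in triangles:
        zmin, zmax = tri[:, 2].min(), tri[:, 2].max()
        for k in range(n_slabs):
            lo, hi = edges[k], edges[k + 1]
            if zmax < lo or zmin > hi:
                continue
            poly = tri
            if zmin < lo:
                poly = clip_polygon_z(poly, lo, keep_above=True)
            if len(poly) >= 3 and zmax > hi:
                poly = clip_polygon_z(poly, hi, keep_above=False)
            if len(poly) >= 3:
                areas[k] += polygon_area_3d(poly)
    return areas
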