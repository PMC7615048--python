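"""2D polygon primitives for the nuclear-mechanics model.

All lengths are expressed in units of G1∅, the diameter of a spherical
G1-phase nucleus; areas are in G1∅².  The apical-basal axis is ``z``
(``z = 0`` at the basal surface, increasing apically) and ``x`` is the
lateral coordinate.

Nuclei are represented as convex 20-sided polygons stored as
``(20, 2)`` float arrays with counter-clockwise vertex order.  The
vertex count is fixed everywhere: operations that would change it
(division, re-polygonisation) resample the boundary back to 20 vertices
at equal arc length.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon as ShapelyPolygon

N_VERTICES = 20
#: relative convexity tolerance, scaled by the squared mean edge length
CONVEXITY_TOL = 1e-8


class GeometryError(ValueError):
    """Invalid or degenerate geometry passed to a polygon primitive."""


def as_polygon(vertices) -> np.ndarray:
    """Validate and return a ``(20, 2)`` CCW vertex array.

    Raises
    ------
    GeometryError
        if the vertex count is not 20, a coordinate is non-finite, or
        the signed area is not positive (clockwise or degenerate input).
    """
    v = np.asarray(vertices, dtype=float)
    if v.shape != (N_VERTICES, 2):
        raise GeometryError(f"expected ({N_VERTICES}, 2) vertices, got {v.shape}")
    if not np.all(np.isfinite(v)):
        raise GeometryError("non-finite vertex coordinate")
    if polygon_area(v) <= 0:
        raise GeometryError("vertices must be counter-clockwise with positive area")
    return v


def polygon_area(p: np.ndarray) -> float:
    """Signed shoelace area; positive for counter-clockwise input."""
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise GeometryError("non-finite vertex coordinate")
    x, z = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(z, -1) - np.roll(x, -1) * z))


def polygon_centroid(p: np.ndarray) -> np.ndarray:
    """Area-weighted centroid of a simple polygon.

    Raises
    ------
    GeometryError
        for near-zero-area (degenerate) polygons, where the centroid is
        ill-conditioned.
    """
    p = np.asarray(p, dtype=float)
    a = polygon_area(p)
    scale2 = float(np.max(np.ptp(p, axis=0))) ** 2
    if abs(a) <= 1e-12 * max(scale2, 1e-12):
        raise GeometryError("degenerate polygon: near-zero area")
    x, z = p[:, 0], p[:, 1]
    xn, zn = np.roll(x, -1), np.roll(z, -1)
    w = x * zn - xn * z
    cx = float(np.sum((x + xn) * w)) / (6.0 * a)
    cz = float(np.sum((z + zn) * w)) / (6.0 * a)
    return np.array([cx, cz])


def edge_lengths(p: np.ndarray) -> np.ndarray:
    """Lengths of the 20 edges, edge ``i`` joining vertex ``i`` to ``i+1``."""
    d = np.roll(p, -1, axis=0) - p
    return np.hypot(d[:, 0], d[:, 1])


def cross_products(p: np.ndarray) -> np.ndarray:
    """Consecutive-edge cross products; all ≥ 0 for a convex CCW polygon."""
    e = np.roll(p, -1, axis=0) - p
    e_next = np.roll(e, -1, axis=0)
    return e[:, 0] * e_next[:, 1] - e[:, 1] * e_next[:, 0]


def is_convex(p: np.ndarray, tol: float = CONVEXITY_TOL) -> bool:
    """Convexity predicate with a scale-free tolerance.

    True iff every consecutive-edge cross product is ≥ ``-tol * L²``
    where ``L`` is the mean edge length, so that the test is invariant
    under uniform rescaling.
    """
    p = np.asarray(p, dtype=float)
    L = float(np.mean(edge_lengths(p)))
    return bool(np.all(cross_products(p) >= -tol * L * L))


def max_extent(p: np.ndarray) -> float:
    """Largest pairwise vertex distance (the polygon's diameter)."""
    p = np.asarray(p, dtype=float)
    d = p[:, None, :] - p[None, :, :]
    return float(np.sqrt(np.max(np.sum(d * d, axis=-1))))


def to_shapely(p: np.ndarray) -> ShapelyPolygon:
    """Shapely polygon from vertices, repaired if marginally non-simple."""
    sp = ShapelyPolygon(np.asarray(p, dtype=float))
    if not sp.is_valid:
        sp = sp.buffer(0)
    return sp


def overlap_area(p: np.ndarray, q: np.ndarray) -> float:
    """Area of the intersection of two polygons; 0 if disjoint."""
    sp, sq = to_shapely(p), to_shapely(q)
    return float(sp.intersection(sq).area)


def regular_polygon(center, area: float, phase: float = 0.0) -> np.ndarray:
    """Regular 20-gon of the requested area centred at ``center``.

    ``phase`` rotates the vertex placement (radians); the default puts
    the first vertex on the +x axis.
    """
    if not area > 0:
        raise GeometryError(f"area must be positive, got {area}")
    center = np.asarray(center, dtype=float)
    n = N_VERTICES
    # area of a regular n-gon with circumradius r: (n/2) r² sin(2π/n)
    r = np.sqrt(2.0 * area / (n * np.sin(2.0 * np.pi / n)))
    theta = phase + 2.0 * np.pi * np.arange(n) / n
    return center + r * np.column_stack([np.cos(theta), np.sin(theta)])


def point_segment_distance(pt, a, b) -> float:
    """Euclidean distance from ``pt`` to the closed segment ``[a, b]``."""
    pt, a, b = (np.asarray(u, dtype=float) for u in (pt, a, b))
    d = b - a
    L2 = float(d @ d)
    if L2 == 0.0:
        raise GeometryError("degenerate segment: coincident endpoints")
    t = np.clip(float((pt - a) @ d) / L2, 0.0, 1.0)
    return float(np.hypot(*(pt - (a + t * d))))


def resample_to_20(boundary: np.ndarray) -> np.ndarray:
    """Resample a closed CCW boundary polyline to 20 equally spaced vertices.

    ``boundary`` is an (m, 2) array of distinct vertices (not repeating
    the first).  Vertices are placed at equal arc length along the
    boundary, starting at the first input vertex.
    """
    b = np.asarray(boundary, dtype=float)
    closed = np.vstack([b, b[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    if total <= 0:
        raise GeometryError("degenerate boundary: zero perimeter")
    s = np.linspace(0.0, total, N_VERTICES, endpoint=False)
    idx = np.searchsorted(cum, s, side="right") - 1
    idx = np.clip(idx, 0, len(seglen) - 1)
    frac = (s - cum[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0)
    return closed[idx] + frac[:, None] * seg[idx]


def scale_to_area(p: np.ndarray, area: float) -> np.ndarray:
    """Uniformly scale a polygon about its centroid to the exact area."""
    if not area > 0:
        raise GeometryError(f"area must be positive, got {area}")
    current = polygon_area(p)
    if current <= 0:
        raise GeometryError("cannot rescale a collapsed or inverted polygon")
    c = polygon_centroid(p)
    s = np.sqrt(area / current)
    return c + s * (p - c)
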