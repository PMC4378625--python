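"""Exact 2-D computational geometry on point sets.

These primitives back the canopy shape descriptors: convex hull, calliper
length (hull diameter) and minimum enclosing circle.  They are deliberately
exact on integer-valued pixel coordinates — the hull keeps only extreme
points (cross products on integer coordinates are exact in double
precision), polygon areas use the shoelace formula, and the enclosing
circle is the true smallest circle via a Welzl-style incremental
construction, not an approximation.

Points are ``(x, y)`` pairs; the raster convention elsewhere in the
package maps ``x = column`` and ``y = row`` (origin top-left).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "convex_hull",
    "polygon_area",
    "calliper_length",
    "min_enclosing_circle",
]


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y) pairs")
    if len(pts) == 0:
        raise ValueError("empty point set")
    return pts


def _cross(o, a, b) -> float:
    """z-component of (a-o) x (b-o)."""
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points) -> np.ndarray:
    """Convex hull by Andrew's monotone chain.

    Returns only the extreme points, ordered along the boundary.  Collinear
    input degenerates to the two endpoints of the segment; a single
    (possibly repeated) point to itself.
    """
    pts = np.unique(_as_points(points), axis=0)
    if len(pts) <= 2:
        return pts
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]

    def _chain(seq):
        out: list = []
        for p in seq:
            # <= pops collinear points: only strict corners survive
            while len(out) >= 2 and _cross(out[-2], out[-1], p) <= 0:
                out.pop()
            out.append(p)
        return out

    lower = _chain(pts)
    upper = _chain(pts[::-1])
    return np.array(lower[:-1] + upper[:-1])


def polygon_area(vertices) -> float:
    """Shoelace area of a simple polygon; < 3 vertices (degenerate) gives 0."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def calliper_length(points) -> float:
    """Maximum pairwise distance (hull diameter).

    Computed as the all-pairs maximum over hull vertices, which equals the
    maximum over every input point because the diameter of a set is
    attained at extreme points.  Single point -> 0.
    """
    hull = convex_hull(points)
    if len(hull) == 1:
        return 0.0
    d2 = np.sum((hull[:, None, :] - hull[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


# --- minimum enclosing circle -------------------------------------------------

_REL_EPS = 1e-12


def _contains(circle, p) -> bool:
    cx, cy, r = circle
    return math.hypot(p[0] - cx, p[1] - cy) <= r * (1 + _REL_EPS) + _REL_EPS


def _circum(a, b, c):
    """Circumcircle of three points, or None when collinear."""
    d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if d == 0.0:
        return None
    a2 = a[0] ** 2 + a[1] ** 2
    b2 = b[0] ** 2 + b[1] ** 2
    c2 = c[0] ** 2 + c[1] ** 2
    ux = (a2 * (b[1] - c[1]) + b2 * (c[1] - a[1]) + c2 * (a[1] - b[1])) / d
    uy = (a2 * (c[0] - b[0]) + b2 * (a[0] - c[0]) + c2 * (b[0] - a[0])) / d
    r = max(
        math.hypot(a[0] - ux, a[1] - uy),
        math.hypot(b[0] - ux, b[1] - uy),
        math.hypot(c[0] - ux, c[1] - uy),
    )
    return (ux, uy, r)


def _circle_two(a, b):
    cx = (a[0] + b[0]) / 2.0
    cy = (a[1] + b[1]) / 2.0
    r = max(math.hypot(a[0] - cx, a[1] - cy), math.hypot(b[0] - cx, b[1] - cy))
    return (cx, cy, r)


def _mec_two_fixed(pts, p, q):
    """Smallest circle through p and q containing pts[:i]."""
    circ = _circle_two(p, q)
    left = None
    right = None
    px, py = p
    qx, qy = q
    for s in pts:
        if _contains(circ, s):
            continue
        cross = (qx - px) * (s[1] - py) - (qy - py) * (s[0] - px)
        c = _circum(p, q, s)
        if c is None:
            continue
        cc = (qx - px) * (c[1] - py) - (qy - py) * (c[0] - px)
        if cross > 0 and (left is None or cc > (qx - px) * (left[1] - py) - (qy - py) * (left[0] - px)):
            left = c
        elif cross < 0 and (right is None or cc < (qx - px) * (right[1] - py) - (qy - py) * (right[0] - px)):
            right = c
    if left is None and right is None:
        return circ
    if left is None:
        return right
    if right is None:
        return left
    return left if left[2] <= right[2] else right


def _mec_one_fixed(pts, p):
    """Smallest circle through p containing the prefix pts."""
    circ = (p[0], p[1], 0.0)
    for i, q in enumerate(pts):
        if not _contains(circ, q):
            if circ[2] == 0.0:
                circ = _circle_two(p, q)
            else:
                circ = _mec_two_fixed(pts[:i], p, q)
    return circ


def min_enclosing_circle(points):
    """Smallest circle containing every point.

    Welzl-type incremental algorithm (expected linear time) run on the
    convex-hull vertices; returns ``((cx, cy), radius)`` exact to ~1e-12
    relative.  A deterministic seeded shuffle decorrelates insertion order
    from the raster scan order, so results are reproducible.
    """
    hull = convex_hull(points)
    pts = [(float(x), float(y)) for x, y in hull]
    if len(pts) == 1:
        return (pts[0], 0.0)
    order = np.random.default_rng(1009).permutation(len(pts))
    pts = [pts[i] for i in order]
    circ = None
    for i, p in enumerate(pts):
        if circ is None or not _contains(circ, p):
            circ = _mec_one_fixed(pts[:i], p)
    return ((circ[0], circ[1]), circ[2])
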