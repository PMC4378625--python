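"""Independent brute-force oracles for the geometry test suites.

Deliberately naive: exhaustive half-plane tests for hull vertices,
exhaustive pair/triple candidate enumeration for the minimum enclosing
circle, all-pairs maxima for the calliper, and a direct eigendecomposition
for eccentricity.  Vectorised with numpy only so the exhaustive suites
stay fast, but structurally independent of the package implementations.
"""

from itertools import combinations

import numpy as np


def hull_vertices_bruteforce(pts: np.ndarray) -> set:
    """Extreme points via the O(n^3) directed-edge half-plane test.

    Edge (i, j) is on the hull iff every other point lies strictly to its
    left, or on the line but within the segment.  Hull vertices are the
    endpoints of such edges.
    """
    P = np.asarray(pts, dtype=float)
    n = len(P)
    if n == 1:
        return {tuple(P[0])}
    verts = set()
    for i in range(n):
        a = P[i]
        d = P - a  # vectors a->k
        for j in range(n):
            if j == i:
                continue
            b = P[j]
            ab = b - a
            cross = ab[0] * d[:, 1] - ab[1] * d[:, 0]
            on_line = cross == 0
            between = (
                (np.minimum(a[0], b[0]) <= P[:, 0])
                & (P[:, 0] <= np.maximum(a[0], b[0]))
                & (np.minimum(a[1], b[1]) <= P[:, 1])
                & (P[:, 1] <= np.maximum(a[1], b[1]))
            )
            ok = (cross > 0) | (on_line & between)
            ok[i] = ok[j] = True
            if ok.all():
                verts.add(tuple(a))
                verts.add(tuple(b))
    return verts


def polygon_area_shoelace(vertices) -> float:
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def mec_bruteforce(pts: np.ndarray):
    """Smallest enclosing circle by exhaustive pair + triple enumeration.

    Every minimum enclosing circle is determined by two (diametral) or
    three boundary points; enumerate all candidates and keep the smallest
    that encloses everything.  Returns (cx, cy, r).
    """
    P = np.asarray(pts, dtype=float)
    n = len(P)
    if n == 1:
        return (P[0, 0], P[0, 1], 0.0)
    cands = []
    ii, jj = np.triu_indices(n, 1)
    mid = (P[ii] + P[jj]) / 2.0
    r_pair = np.hypot(*(P[ii] - mid).T)
    cands.append(np.column_stack([mid, r_pair]))
    if n >= 3:
        tri = np.array(list(combinations(range(n), 3)))
        a, b, c = P[tri[:, 0]], P[tri[:, 1]], P[tri[:, 2]]
        d = 2.0 * (a[:, 0] * (b[:, 1] - c[:, 1]) + b[:, 0] * (c[:, 1] - a[:, 1]) + c[:, 0] * (a[:, 1] - b[:, 1]))
        ok = d != 0
        a, b, c, d = a[ok], b[ok], c[ok], d[ok]
        a2, b2, c2 = (a**2).sum(1), (b**2).sum(1), (c**2).sum(1)
        ux = (a2 * (b[:, 1] - c[:, 1]) + b2 * (c[:, 1] - a[:, 1]) + c2 * (a[:, 1] - b[:, 1])) / d
        uy = (a2 * (c[:, 0] - b[:, 0]) + b2 * (a[:, 0] - c[:, 0]) + c2 * (b[:, 0] - a[:, 0])) / d
        r_tri = np.maximum.reduce(
            [np.hypot(a[:, 0] - ux, a[:, 1] - uy), np.hypot(b[:, 0] - ux, b[:, 1] - uy), np.hypot(c[:, 0] - ux, c[:, 1] - uy)]
        )
        cands.append(np.column_stack([ux, uy, r_tri]))
    C = np.vstack(cands)
    best = None
    for s in range(0, len(C), 20000):
        chunk = C[s : s + 20000]
        dist = np.hypot(chunk[:, None, 0] - P[None, :, 0], chunk[:, None, 1] - P[None, :, 1])
        encl = (dist <= chunk[:, 2:3] * (1 + 1e-12) + 1e-12).all(axis=1)
        if encl.any():
            k = int(np.argmin(np.where(encl, chunk[:, 2], np.inf)))
            if best is None or chunk[k, 2] < best[2]:
                best = tuple(chunk[k])
    return best


def calliper_bruteforce(pts: np.ndarray) -> float:
    """Max pairwise distance over every point (not just hull vertices)."""
    P = np.asarray(pts, dtype=float)
    d2 = ((P[:, None, :] - P[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def eccentricity_bruteforce(pts: np.ndarray) -> float:
    """Direct eigendecomposition of the 2x2 second-moment matrix."""
    P = np.asarray(pts, dtype=float)
    centred = P - P.mean(axis=0)
    m = centred.T @ centred / len(P)
    lam2, lam1 = np.sort(np.linalg.eigvalsh(m))
    return float(np.sqrt(1.0 - max(lam2, 0.0) / lam1))


def random_pixel_mask(rng: np.random.Generator, max_px: int = 100, box: int = 40) -> np.ndarray:
    """Random sparse pixel scatter: unique integer (x, y) centres."""
    n = int(rng.integers(3, max_px + 1))
    return np.unique(rng.integers(0, box, size=(n, 2)), axis=0).astype(float)
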