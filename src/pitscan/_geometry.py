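"""Minimum enclosing circle (Welzl's algorithm).

The slice-centre fit needs the smallest circle containing the outer contour
of the metal core: unlike a centroid, it is governed by the intact rim and is
therefore robust to inward material loss (pits bias a centroid toward the
intact side). Expected O(n) after a deterministic shuffle; the convex hull is
taken first for large point sets since only hull vertices can support the
circle.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

_EPS = 1e-9


def _circle_two(p, q):
    c = (p + q) / 2.0
    r = float(np.hypot(*(p - c)))
    return c, r


def _circumcircle(a, b, c):
    """Circle through three points; None if (near-)collinear."""
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.hypot(*(a - center)))


def _in_circle(p, c, r):
    return np.hypot(*(p - c)) <= r * (1.0 + _EPS) + _EPS


def _mec_two_fixed(pts, q1, q2):
    c, r = _circle_two(q1, q2)
    for p in pts:
        if not _in_circle(p, c, r):
            cc = _circumcircle(q1, q2, p)
            if cc is not None:
                c, r = cc
            else:  # collinear: widest pair wins
                for pair in ((q1, p), (q2, p)):
                    c2, r2 = _circle_two(*pair)
                    if r2 > r and _in_circle(q1, c2, r2) and _in_circle(q2, c2, r2):
                        c, r = c2, r2
    return c, r


def _mec_one_fixed(pts, q):
    c, r = q.copy(), 0.0
    for j, p in enumerate(pts):
        if not _in_circle(p, c, r):
            c, r = _mec_two_fixed(pts[:j], q, p)
    return c, r


def min_enclosing_circle(points) -> tuple[np.ndarray, float]:
    """Smallest circle enclosing all ``points`` (array-like, shape (n, 2)).

    Returns ``(center, radius)`` with ``center`` an (x, y) array. Deterministic:
    the incremental order is a fixed-seed shuffle of the convex-hull vertices.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    if len(pts) == 1:
        return pts[0].copy(), 0.0
    if len(pts) > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear input: fall through with all points
    rng = np.random.default_rng(0)
    pts = pts[rng.permutation(len(pts))]

    c, r = pts[0].copy(), 0.0
    for i, p in enumerate(pts):
        if not _in_circle(p, c, r):
            c, r = _mec_one_fixed(pts[:i], p)
    return c, r


def circular_runs(mask) -> list[tuple[int, ...]]:
    """Maximal runs of True in a boolean array treated as circular.

    A run crossing the end/start seam is returned as one run, ordered from its
    first index after the seam-side gap. An all-True mask is a single run
    starting at index 0.
    """
    m = np.asarray(mask, dtype=bool)
    n = len(m)
    if n == 0 or not m.any():
        return []
    if m.all():
        return [tuple(range(n))]
    # rotate so position 0 is False, split linearly, rotate back
    start = int(np.flatnonzero(~m)[0])
    rolled = np.roll(m, -start)
    runs = []
    idx = np.flatnonzero(rolled)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    for chunk in np.split(idx, breaks + 1):
        runs.append(tuple((int(i) + start) % n for i in chunk))
    runs.sort(key=lambda r: r[0])
    return runs
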