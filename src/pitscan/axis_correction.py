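"""Oblique-mounting correction: per-slice centre points on a straight axis.

A specimen mounted slightly tilted in the scanner drifts across the field of
view from slice to slice. Measuring every radial depth from a per-slice
centroid would fold that drift — and any asymmetric material loss — into the
depth profile. Instead the undegraded axis is estimated once, from the fitted
centres of the first and last slice, and every intermediate centre is linearly
interpolated along that line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from ._geometry import min_enclosing_circle
from .errors import DetectionError, InputError


@dataclass
class CenterLine:
    """Straight specimen axis through the fitted end-slice centres.

    ``s`` is the per-slice x step, ``m``/``n`` the slope and intercept of
    y(x) (``None`` for a vertical line), ``centers`` one (x, y) per slice.
    """

    p1: tuple[float, float]
    p2: tuple[float, float]
    n_slices: int
    s: float
    m: float | None
    n: float | None
    centers: np.ndarray = field(repr=False)

    def center(self, layer: int) -> np.ndarray:
        return self.centers[layer]


def largest_component(slice2d: np.ndarray) -> np.ndarray:
    """Boolean mask of the largest connected foreground component."""
    arr = np.asarray(slice2d, dtype=bool)
    if not arr.any():
        raise DetectionError("slice contains no foreground voxels")
    labels = measure.label(arr, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def fit_slice_center(slice2d) -> tuple[float, float]:
    """Centre of the minimum enclosing circle of the largest blob's contour.

    The enclosing circle rides on the intact rim, so inward pits barely move
    the centre — a centroid would drift toward the remaining material.
    Returns (x, y) in voxel coordinates.
    """
    comp = largest_component(slice2d)
    contours = measure.find_contours(comp.astype(float), 0.5)
    if not contours:
        raise DetectionError("no contour found in slice")
    contour = max(contours, key=len)
    pts_xy = contour[:, ::-1]  # (row, col) -> (x, y)
    center, _ = min_enclosing_circle(pts_xy)
    return float(center[0]), float(center[1])


def build_center_line(first, last, n_slices: int) -> CenterLine:
    """Interpolate per-slice centres on the line through two end centres.

    x advances in equal steps s = (x2 − x1)/(n_slices − 1) so the interpolant
    passes through both measured endpoints; y follows the line y = m·x + n.
    A vertical line (x1 == x2) falls back to direct linear interpolation of y.
    """
    if n_slices < 2:
        raise InputError("n_slices must be >= 2")
    x1, y1 = float(first[0]), float(first[1])
    x2, y2 = float(last[0]), float(last[1])
    s = (x2 - x1) / (n_slices - 1)
    i = np.arange(n_slices, dtype=float)
    if x1 == x2:
        m = n = None
        xs = np.full(n_slices, x1)
        ys = y1 + i * (y2 - y1) / (n_slices - 1)
    else:
        m = (y2 - y1) / (x2 - x1)
        n = y1 - m * x1
        xs = x1 + i * s
        ys = xs * m + n
    centers = np.column_stack([xs, ys])
    return CenterLine(p1=(x1, y1), p2=(x2, y2), n_slices=n_slices,
                      s=s, m=m, n=n, centers=centers)


def estimate_center_line(volume, center_slices: int = 1) -> CenterLine:
    """Fit the axis from the first and last slice(s) of a binary volume.

    ``center_slices`` > 1 averages the enclosing-circle centres of that many
    slices at each end to damp single-slice noise (default 1 reproduces the
    plain two-anchor construction).
    """
    nz = volume.n_slices
    k = max(1, min(int(center_slices), nz // 2))
    first = np.mean([fit_slice_center(volume.data[j]) for j in range(k)], axis=0)
    last = np.mean([fit_slice_center(volume.data[nz - 1 - j]) for j in range(k)], axis=0)
    return build_center_line(first, last, nz)
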