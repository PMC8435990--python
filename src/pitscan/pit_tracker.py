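"""Bond 2D pit segments across layers into 3D pits and measure them.

A pit that spans several cross-sections appears as one angular run of the pit
mask per layer. Two runs in adjacent layers that overlap in angular range are
bonded into the same 3D pit; bonding is transitive (a pit that splits and
rejoins is one pit, matching the observed coalescence of small pits into
larger ones). Each 3D pit then gets a deepest point, an opening area and a
volume, and only pits deeper than 50 µm survive the severity filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import radians

import numpy as np

from ._geometry import circular_runs
from .errors import InputError

N_BINS = 180


@dataclass
class PitSegment2D:
    """One maximal circular run of the pit mask in a single layer."""

    layer: int
    angle_indices: tuple[int, ...]   # contiguous under circular adjacency
    depths: np.ndarray = field(repr=False)  # µm, aligned with angle_indices

    def index_set(self) -> frozenset[int]:
        return frozenset(self.angle_indices)


@dataclass
class Pit3D:
    """A bonded multi-layer pit."""

    segments: list[PitSegment2D]
    d_max: float                          # µm
    deepest_point: tuple[int, int, float]  # (layer, angle index, depth µm)
    n_layers: int
    opening_area: float = float("nan")    # µm², filled by pit_geometry
    volume: float = float("nan")          # µm³

    @property
    def layers(self) -> list[int]:
        return sorted({s.layer for s in self.segments})

    def cells(self):
        """Iterate (layer, angle_index, depth) over all member cells."""
        for seg in self.segments:
            for idx, dep in zip(seg.angle_indices, seg.depths):
                yield seg.layer, idx, float(dep)


def extract_segments(profiles) -> list[PitSegment2D]:
    """One segment per maximal circular run of P == 1, per layer."""
    segments = []
    for p in profiles:
        for run in circular_runs(p.P):
            segments.append(PitSegment2D(
                layer=p.layer,
                angle_indices=tuple(run),
                depths=np.asarray([p.d[i] for i in run], dtype=float)))
    segments.sort(key=lambda s: (s.layer, s.angle_indices[0]))
    return segments


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def bond_segments(segments, min_overlap: int = 1) -> list[Pit3D]:
    """Merge segments in adjacent layers whose angular ranges overlap.

    Overlap means at least ``min_overlap`` shared angle indices (circular).
    Bonding is transitive: the pit set is the connected components of the
    layer-adjacency overlap graph, so Y-shaped splits/merges stay one pit.
    """
    segments = sorted(segments, key=lambda s: (s.layer, s.angle_indices[0]))
    uf = _UnionFind(len(segments))
    by_layer: dict[int, list[int]] = {}
    for i, s in enumerate(segments):
        by_layer.setdefault(s.layer, []).append(i)
    for layer, idxs in by_layer.items():
        for i in idxs:
            for j in by_layer.get(layer + 1, ()):
                if len(segments[i].index_set() & segments[j].index_set()) >= min_overlap:
                    uf.union(i, j)

    groups: dict[int, list[PitSegment2D]] = {}
    for i, s in enumerate(segments):
        groups.setdefault(uf.find(i), []).append(s)

    pits = []
    for segs in groups.values():
        segs.sort(key=lambda s: (s.layer, s.angle_indices[0]))
        best = (np.inf, np.inf, -np.inf)  # (layer, angle) ties -> lowest
        for seg in segs:
            for idx, dep in zip(seg.angle_indices, seg.depths):
                if dep > best[2] or (dep == best[2] and (seg.layer, idx) < best[:2]):
                    best = (seg.layer, idx, float(dep))
        pits.append(Pit3D(segments=segs, d_max=best[2],
                          deepest_point=(int(best[0]), int(best[1]), best[2]),
                          n_layers=len({s.layer for s in segs})))
    pits.sort(key=lambda p: (p.deepest_point[0], p.deepest_point[1]))
    return pits


def filter_pits(pits, min_depth_um: float = 50.0) -> list[Pit3D]:
    """Keep pits with maximum depth strictly greater than ``min_depth_um``."""
    return [p for p in pits if p.d_max > min_depth_um]


def pit_geometry(pit: Pit3D, r1_per_layer: dict, slice_thickness_um: float,
                 angular_step_deg: float = 2.0, mid_depth_arc: bool = True):
    """Opening area, volume and deepest point of one 3D pit.

    Quadrature over member cells: each (layer, angle) cell spans an arc
    element Δθ·r1(layer) by one slice thickness. The opening area sums the
    arc elements at the fitted radius; the volume sums depth × arc element
    taken at the mid-depth radius r1 − depth/2, a second-order correction for
    the inward taper of the wedge (``mid_depth_arc=False`` selects the plain
    rectangle rule at r1). Updates the pit in place and returns
    ``(opening_area, volume, deepest_point)``.
    """
    dtheta = radians(angular_step_deg)
    opening = 0.0
    volume = 0.0
    for layer, idx, depth in pit.cells():
        if layer not in r1_per_layer:
            raise InputError(f"missing r1 for layer {layer}")
        r1 = float(r1_per_layer[layer])
        arc_r = r1 - depth / 2.0 if mid_depth_arc else r1
        opening += dtheta * r1 * slice_thickness_um
        volume += depth * dtheta * max(arc_r, 0.0) * slice_thickness_um
    pit.opening_area = opening
    pit.volume = volume
    return opening, volume, pit.deepest_point


def measure_pits(pits, profiles, voxel_size_um: float,
                 angular_step_deg: float = 2.0, mid_depth_arc: bool = True):
    """Apply :func:`pit_geometry` to every pit using per-layer fitted radii."""
    r1 = {p.layer: p.r1_um for p in profiles}
    for pit in pits:
        pit_geometry(pit, r1, voxel_size_um, angular_step_deg, mid_depth_arc)
    return pits


def pits_to_frame(pits):
    """Pit catalogue: one row per pit."""
    import pandas as pd

    rows = []
    for i, p in enumerate(pits):
        n_cells = sum(1 for _ in p.cells())
        rows.append({
            "pit_id": i,
            "n_layers": p.n_layers,
            "n_cells": n_cells,
            "d_max_um": p.d_max,
            "opening_area_um2": p.opening_area,
            "volume_um3": p.volume,
            "deepest_layer": p.deepest_point[0],
            "deepest_angle_deg": p.deepest_point[1] * (360.0 / N_BINS),
        })
    return pd.DataFrame(rows, columns=[
        "pit_id", "n_layers", "n_cells", "d_max_um", "opening_area_um2",
        "volume_um3", "deepest_layer", "deepest_angle_deg"])
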