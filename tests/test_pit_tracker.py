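"""3D bonding of pit segments, severity filtering and pit geometry."""

import itertools
from math import pi

import numpy as np
import pytest

import pitscan as ps
from pitscan.errors import InputError
from pitscan.pit_tracker import PitSegment2D, pits_to_frame
from pitscan.slice_profile import SliceProfile


def make_profile(layer, pit_bins=(), depth=200.0, r1=1400.0, r0=1500.0):
    d = np.zeros(180)
    for b in pit_bins:
        d[b % 180] = depth
    return SliceProfile(layer=layer, center=(0.0, 0.0), r_enclosing_um=r1,
                        r1_um=r1, r0_um=r0, d=d,
                        total_penetration=d + (r0 - r1),
                        P=ps.mark_pits(d), flagged=np.zeros(180, dtype=bool))


def seg(layer, indices, depth=200.0):
    return PitSegment2D(layer=layer, angle_indices=tuple(i % 180 for i in indices),
                        depths=np.full(len(indices), float(depth)))


def brute_force_components(segments):
    """Union-find oracle: connected components of the bipartite overlap graph."""
    n = len(segments)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        si, sj = segments[i], segments[j]
        if abs(si.layer - sj.layer) == 1 and set(si.angle_indices) & set(sj.angle_indices):
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestExtractSegments:
    def test_no_pits_no_segments(self):
        profiles = [make_profile(i, pit_bins=()) for i in range(3)]
        assert ps.extract_segments(profiles) == []

    def test_two_separated_runs_two_segments(self):
        profiles = [make_profile(0, pit_bins=[10, 11, 40, 41, 42])]
        segs = ps.extract_segments(profiles)
        assert [s.angle_indices for s in segs] == [(10, 11), (40, 41, 42)]

    def test_seam_run_is_one_segment(self):
        profiles = [make_profile(0, pit_bins=[178, 179, 0, 1])]
        segs = ps.extract_segments(profiles)
        assert len(segs) == 1
        assert segs[0].angle_indices == (178, 179, 0, 1)


class TestBondSegments:
    def test_stacked_segments_single_pit(self):
        segs = [seg(layer, range(10, 16)) for layer in range(3, 8)]
        pits = ps.bond_segments(segs)
        assert len(pits) == 1 and pits[0].n_layers == 5

    def test_disjoint_angles_two_pits(self):
        pits = ps.bond_segments([seg(3, [10, 11, 12]), seg(4, [40, 41, 42])])
        assert len(pits) == 2

    def test_same_range_nonadjacent_layers_stay_separate(self):
        pits = ps.bond_segments([seg(0, [10, 11]), seg(2, [10, 11])])
        assert len(pits) == 2

    def test_y_topology_is_one_pit(self):
        segs = [seg(1, range(10, 21)), seg(2, [10, 11, 12]), seg(2, [18, 19, 20])]
        pits = ps.bond_segments(segs)
        assert len(pits) == 1
        assert sum(1 for _ in pits[0].cells()) == 17

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        segs = []
        for _ in range(rng.integers(5, 25)):
            layer = int(rng.integers(0, 8))
            start = int(rng.integers(0, 180))
            segs.append(seg(layer, range(start, start + int(rng.integers(1, 12)))))
        pits = ps.bond_segments(segs)
        got = {frozenset(id(s) for s in p.segments) for p in pits}
        segs_sorted = sorted(segs, key=lambda s: (s.layer, s.angle_indices[0]))
        oracle = brute_force_components(segs_sorted)
        expect = {frozenset(id(segs_sorted[i]) for i in comp) for comp in oracle}
        assert got == expect

    def test_layer_reversal_leaves_pit_set_unchanged(self):
        rng = np.random.default_rng(11)
        segs = []
        for _ in range(15):
            start = int(rng.integers(0, 180))
            segs.append(seg(int(rng.integers(0, 6)),
                            range(start, start + int(rng.integers(1, 9)))))
        pits_fwd = ps.bond_segments(segs)
        max_layer = max(s.layer for s in segs)
        rev = [PitSegment2D(max_layer - s.layer, s.angle_indices, s.depths)
               for s in segs]
        pits_rev = ps.bond_segments(rev)
        sig_fwd = sorted((p.n_layers, sum(1 for _ in p.cells()), p.d_max)
                         for p in pits_fwd)
        sig_rev = sorted((p.n_layers, sum(1 for _ in p.cells()), p.d_max)
                         for p in pits_rev)
        assert sig_fwd == sig_rev

    def test_deepest_point_tie_breaks_to_lowest_layer_then_angle(self):
        segs = [seg(2, [30, 31], depth=120.0), seg(3, [30, 31], depth=120.0)]
        pits = ps.bond_segments(segs)
        assert pits[0].deepest_point == (2, 30, 120.0)


class TestFilterPits:
    def test_strictly_greater_than_threshold(self):
        pits = ps.bond_segments([seg(0, [5], depth=30.0), seg(2, [50], depth=50.0),
                                 seg(4, [100], depth=70.0)])
        kept = ps.filter_pits(pits, min_depth_um=50.0)
        assert [p.d_max for p in kept] == [70.0]

    def test_empty_and_identity(self):
        assert ps.filter_pits([], 50.0) == []
        pits = ps.bond_segments([seg(0, [5], depth=30.0)])
        assert ps.filter_pits(pits, min_depth_um=0.0) == pits


class TestPitGeometry:
    def test_single_cell_opening_hand_calculation(self):
        pits = ps.bond_segments([seg(0, [10], depth=100.0)])
        opening, volume, deepest = ps.pit_geometry(
            pits[0], {0: 1400.0}, slice_thickness_um=15.0)
        assert opening == pytest.approx((pi / 90) * 1400 * 15, rel=1e-12)  # ≈733 µm²
        assert volume == pytest.approx(100 * (pi / 90) * (1400 - 50) * 15, rel=1e-12)
        assert deepest == (0, 10, 100.0)

    def test_rectangle_rule_uses_r1_arc(self):
        pits = ps.bond_segments([seg(0, [10], depth=100.0)])
        _, volume, _ = ps.pit_geometry(pits[0], {0: 1400.0}, 15.0,
                                       mid_depth_arc=False)
        assert volume == pytest.approx(100 * (pi / 90) * 1400 * 15, rel=1e-12)

    def test_zero_depth_zero_volume(self):
        pit = ps.Pit3D(segments=[seg(0, [10], depth=0.0)], d_max=0.0,
                       deepest_point=(0, 10, 0.0), n_layers=1)
        _, volume, _ = ps.pit_geometry(pit, {0: 1400.0}, 15.0)
        assert volume == 0.0

    def test_missing_radius_raises(self):
        pits = ps.bond_segments([seg(7, [10], depth=100.0)])
        with pytest.raises(InputError):
            ps.pit_geometry(pits[0], {0: 1400.0}, 15.0)


def test_cell_bookkeeping_matches_pit_mask():
    """Every masked (layer, angle) cell belongs to exactly one pit."""
    profiles = [make_profile(i, pit_bins=[10, 11, 12, 90, 91], depth=120.0)
                for i in range(4)]
    segs = ps.extract_segments(profiles)
    pits = ps.bond_segments(segs)
    total_cells = sum(1 for p in pits for _ in p.cells())
    assert total_cells == sum(int(p.P.sum()) for p in profiles)


def test_catalogue_frame_columns():
    profiles = [make_profile(i, pit_bins=[10, 11], depth=120.0) for i in range(3)]
    pits = ps.measure_pits(ps.bond_segments(ps.extract_segments(profiles)),
                           profiles, voxel_size_um=15.0)
    frame = pits_to_frame(pits)
    assert len(frame) == 1
    assert frame.loc[0, "n_layers"] == 3
    assert frame.loc[0, "deepest_angle_deg"] == 20.0
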