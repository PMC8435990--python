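"""Per-slice contouring, fitted radius, depth sampling and the pit mask."""

import numpy as np
import pytest

import pitscan as ps
from pitscan._geometry import circular_runs
from pitscan.errors import DegenerateSliceError
from pitscan.slice_profile import ray_distances

from conftest import make_disc


def circle_contour(radius, center=(0.0, 0.0), n=720):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(theta),
                            center[1] + radius * np.sin(theta)])


class TestDetectContour:
    def test_disc_contour_points_at_radius(self):
        disc = make_disc((128, 128), (64, 64), 30)
        contour = ps.detect_contour(disc)
        r = np.hypot(contour[:, 0] - 64, contour[:, 1] - 64)
        assert np.all(np.abs(r - 30) <= 1.0)
        # boundary-pixel oracle: roughly one contour vertex per boundary pixel
        assert 0.7 * 2 * np.pi * 30 < len(contour) < 2.0 * 2 * np.pi * 30

    def test_interior_hole_ignored(self):
        disc = make_disc((128, 128), (64, 64), 30)
        holed = disc & ~make_disc((128, 128), (64, 64), 10)
        assert np.array_equal(ps.detect_contour(holed), ps.detect_contour(disc))

    def test_largest_of_two_components_wins(self):
        img = make_disc((128, 128), (40, 40), 18)      # area ~1000
        img |= make_disc((128, 128), (100, 100), 4)    # area ~50
        contour = ps.detect_contour(img)
        assert np.all(np.hypot(contour[:, 0] - 40, contour[:, 1] - 40) <= 19)


class TestFitReducedRadius:
    def test_perfect_circle_within_one_step(self):
        contour = circle_contour(750.0)
        r1 = ps.fit_reduced_radius(contour, (0, 0), step=15.0)
        assert abs(r1 - 750.0) <= 15.0

    def test_single_notch_does_not_drag_radius(self):
        contour = circle_contour(750.0)
        theta = np.arctan2(contour[:, 1], contour[:, 0]) % (2 * np.pi)
        notch = np.abs(theta - np.pi / 2) < np.radians(1.0)  # one 2° bin
        contour[notch] *= 650.0 / 750.0
        r1 = ps.fit_reduced_radius(contour, (0, 0), step=15.0)
        assert abs(r1 - 750.0) <= 15.0  # 179/180 directions still at 750

    def test_star_radius_between_material_levels(self):
        # 10% of directions reach 700, the rest stop at 650:
        # at 20% material ratio the radius must land in [650, 700)
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        theta_deg = np.degrees(theta)
        # 2°-wide spikes centred on every tenth sampling direction (18 of 180)
        spike = np.abs((theta_deg + 10) % 20 - 10) < 1.0
        radii = np.where(spike, 700.0, 650.0)
        contour = np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
        assert 18 / 180 < 0.20  # exhaustive ray-length histogram: 10% at 700
        r1 = ps.fit_reduced_radius(contour, (0, 0), step=5.0)
        assert 650.0 <= r1 < 700.0

    def test_degenerate_contour_raises(self):
        with pytest.raises(DegenerateSliceError):
            # a single far point: ratio 1/180 never reaches 20%
            ps.fit_reduced_radius(np.array([[100.0, 0.0]]), (0, 0),
                                  step=10.0)


class TestSampleDepths:
    def test_intact_disc_depths_below_one_voxel(self):
        disc = make_disc((128, 128), (64, 64), 40)
        d, tp, flagged = ps.sample_depths(disc, (64, 64), r1_um=40 * 15.0,
                                          r0_um=40 * 15.0, voxel_size_um=15.0)
        assert not flagged.any()
        assert d.max() <= 15.0

    def test_wedge_notch_depth_and_extent(self):
        # 10°-wide wedge notch, radial depth 300 µm (20 voxels) on a 1400 µm disc
        r_vox, depth_vox = 1400 / 15, 300 / 15
        disc = make_disc((220, 220), (110, 110), r_vox)
        yy, xx = np.mgrid[0:220, 0:220]
        ang = np.degrees(np.arctan2(yy - 110.0, xx - 110.0)) % 360
        wedge = (np.hypot(xx - 110, yy - 110) > r_vox - depth_vox) & \
                (np.abs(ang - 90) < 5)
        slice2d = disc & ~wedge
        d, tp, _ = ps.sample_depths(slice2d, (110, 110), r1_um=1400.0,
                                    r0_um=1500.0, voxel_size_um=15.0)
        deep = np.flatnonzero(d > 150)
        assert 4 <= len(deep) <= 7          # five-to-six consecutive 2° bins
        assert np.all(np.diff(deep) == 1)
        assert 45 in deep                   # centred on 90°
        assert d[deep].max() == pytest.approx(300.0, abs=30.0)
        rest = np.setdiff1d(np.arange(180), np.concatenate([deep - 1, deep, deep + 1]))
        assert d[rest].max() <= 15.0

    def test_uniform_loss_absorbed_by_r1(self):
        disc = make_disc((220, 220), (110, 110), 1400 / 15)
        d, tp, _ = ps.sample_depths(disc, (110, 110), r1_um=1400.0,
                                    r0_um=1500.0, voxel_size_um=15.0)
        assert np.all(np.abs(tp - 100.0) <= 15.0)
        assert d.max() <= 15.0

    def test_empty_ray_is_full_depth_and_flagged(self):
        # half-plane of metal: rays pointing away meet nothing
        img = np.zeros((64, 64), dtype=bool)
        img[:, :20] = True
        d, tp, flagged = ps.sample_depths(img, (40, 32), r1_um=300.0,
                                          r0_um=300.0, voxel_size_um=15.0)
        assert flagged.any()
        assert np.all(d[flagged] == 300.0)


class TestMarkPits:
    def test_all_zero_depths_no_pits(self):
        assert not ps.mark_pits(np.zeros(180)).any()

    def test_single_run(self):
        d = np.zeros(180)
        d[10:13] = 200.0
        runs = circular_runs(ps.mark_pits(d, on_threshold_um=0.0))
        assert runs == [(10, 11, 12)]

    def test_seam_wrap_is_one_segment(self):
        d = np.zeros(180)
        d[[178, 179, 0, 1]] = 150.0
        runs = circular_runs(ps.mark_pits(d))
        assert len(runs) == 1 and sorted(runs[0]) == [0, 1, 178, 179]

    def test_mask_count_matches_depth_count(self):
        rng = np.random.default_rng(5)
        d = rng.exponential(20, size=180)
        P = ps.mark_pits(d, on_threshold_um=25.0)
        assert P.sum() == np.count_nonzero(d > 25.0)


def test_rotation_permutes_profile_cyclically():
    """Rotating the cross-section by k·2° shifts d and P and leaves the
    scalar summaries (r1, max depth, run-length multiset) unchanged."""
    base_angle, shift_bins = 90.0, 17
    profiles = []
    for extra in (0.0, shift_bins * 2.0):
        r_vox = 1400 / 15
        disc = make_disc((220, 220), (110, 110), r_vox)
        yy, xx = np.mgrid[0:220, 0:220]
        ang = np.degrees(np.arctan2(yy - 110.0, xx - 110.0)) % 360
        wedge = (np.hypot(xx - 110, yy - 110) > r_vox - 20) & \
                (np.abs((ang - base_angle - extra + 180) % 360 - 180) < 6)
        profiles.append(ps.profile_slice(disc & ~wedge, (110.0, 110.0),
                                         r0_um=1500.0, voxel_size_um=15.0))
    p0, p1 = profiles
    assert abs(p0.r1_um - p1.r1_um) <= 15.0
    assert abs(p0.d.max() - p1.d.max()) <= 15.0
    runs0 = sorted(len(r) for r in circular_runs(p0.d > 50))
    runs1 = sorted(len(r) for r in circular_runs(p1.d > 50))
    assert runs0 == runs1
    shifted = np.roll(p0.d, shift_bins)
    assert np.abs(shifted - p1.d).max() <= 15.0


def test_total_penetration_dominates_pit_depth(analyzed_suite):
    _, _, result = analyzed_suite["three_pits"]
    for p in result.profiles:
        if p.r1_um <= p.r0_um:
            assert np.all(p.total_penetration >= p.d - 1e-9)
            # penetration and depth differ by the uniform-corrosion offset
            interior = (p.d > 0) & (p.d < p.r1_um) & (p.total_penetration > 0)
            if interior.any():
                gap = p.total_penetration[interior] - p.d[interior]
                assert np.allclose(gap, p.r0_um - p.r1_um, atol=1e-6)


def test_ray_distances_subvoxel_accuracy():
    disc = make_disc((220, 220), (110, 110), 1400 / 15)
    dist, flagged = ray_distances(disc, (110.0, 110.0))
    assert not flagged.any()
    err_um = dist * 15.0 - 1400.0
    assert np.abs(err_um).max() < 7.5  # half a voxel
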