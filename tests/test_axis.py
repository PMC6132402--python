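"""RANSAC axis fitting, tip designation, needle plane, in-plane view."""

import itertools

import numpy as np
import pytest

from usneedle.axis import (
    NeedleAxis,
    RansacConfig,
    designate_tip,
    needle_plane,
    ransac_fit,
    render_inplane_view,
)
from usneedle.phantom import PhantomConfig, generate_phantom
from usneedle.volume import AXIAL_UNIT, LabelVolume, UltrasoundVolume


def label_volume_from_indices(indices, shape=(40, 40, 40), voxel=0.5):
    labels = np.zeros(shape, dtype=np.uint8)
    labels[tuple(np.asarray(indices).T)] = 1
    return LabelVolume(labels, voxel)


def brute_force_consensus(points, radius):
    """Exhaustive 2-point enumeration oracle: max inlier count."""
    best = 0
    for a, b in itertools.combinations(range(len(points)), 2):
        d = points[b] - points[a]
        n = np.linalg.norm(d)
        if n < 1e-12:
            continue
        d = d / n
        rel = points - points[a]
        dist = np.linalg.norm(rel - (rel @ d)[:, None] * d, axis=1)
        best = max(best, int((dist <= radius + 1e-12).sum()))
    return best


class TestRansacFit:
    def test_collinear_points_recovered_exactly(self):
        idx = [(i, i, 2 * i) for i in range(12)]
        det = label_volume_from_indices(idx)
        axis = ransac_fit(det, RansacConfig(seed=0))
        assert axis is not None
        assert len(axis.inlier_points_mm) == 12
        true_dir = np.array([1.0, 1.0, 2.0]) / np.linalg.norm([1.0, 1.0, 2.0])
        angle = np.arccos(np.clip(abs(axis.direction @ true_dir), 0, 1))
        assert angle < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_consensus_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        line_idx = [(i, 10 + i // 2, 5) for i in range(20)]
        outliers = rng.integers(25, 39, size=(10, 3))
        det = label_volume_from_indices(list(line_idx) + list(map(tuple, outliers)))
        pts = det.voxel_center_mm(np.argwhere(det.labels))
        radius = 1.0
        cfg = RansacConfig(cylinder_diameter_mm=2.0, n_iterations=2000,
                           seed=seed, refine=False)
        axis = ransac_fit(det, cfg)
        assert axis is not None
        assert len(axis.inlier_points_mm) == brute_force_consensus(pts, radius)

    def test_outliers_excluded_from_inlier_set(self):
        line_idx = [(i, 20, 20) for i in range(20)]
        far = [(5, 35, 35), (10, 2, 2), (15, 30, 5), (18, 5, 30), (3, 33, 12), (7, 12, 33)]
        det = label_volume_from_indices(line_idx + far)
        axis = ransac_fit(det, RansacConfig(seed=1))
        assert axis is not None
        got = set(map(tuple, axis.inlier_indices))
        assert got == set(line_idx)

    def test_single_voxel_is_no_needle(self):
        det = label_volume_from_indices([(5, 5, 5)])
        assert ransac_fit(det, RansacConfig(seed=0)) is None

    def test_below_min_inliers_is_no_needle(self):
        det = label_volume_from_indices([(0, 0, 0), (30, 31, 29), (3, 20, 8)])
        assert ransac_fit(det, RansacConfig(seed=0, min_inliers=5)) is None

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        line = [(i, 8 + i, 30 - i) for i in range(15)]
        noise = list(map(tuple, rng.integers(0, 39, size=(15, 3))))
        det = label_volume_from_indices(line + noise)
        a = ransac_fit(det, RansacConfig(seed=5))
        b = ransac_fit(det, RansacConfig(seed=5))
        assert np.array_equal(a.inlier_indices, b.inlier_indices)
        assert np.allclose(a.direction, b.direction)


class TestDesignateTip:
    def _axis_from_line(self):
        idx = [(i, 4, 4) for i in range(21)]  # lateral span 0..10 mm at 0.5 mm
        det = label_volume_from_indices(idx)
        return ransac_fit(det, RansacConfig(seed=0))

    def test_tip_is_far_endpoint_with_known_entry(self):
        axis = designate_tip(self._axis_from_line(), entry_hint="lateral_min")
        assert abs(axis.length_mm - 10.0) < 1e-9
        assert abs(axis.tip_mm[0] - 10.25) < 1e-9  # deepest voxel center
        assert axis.direction[0] > 0

    def test_reversing_entry_hint_flips_tip_and_direction(self):
        a = designate_tip(self._axis_from_line(), entry_hint="lateral_min")
        b = designate_tip(self._axis_from_line(), entry_hint="lateral_max")
        assert np.allclose(a.tip_mm, b.entry_mm)
        assert np.allclose(a.direction, -b.direction)

    def test_auto_entry_picks_nearest_face(self):
        axis = designate_tip(self._axis_from_line(), entry_hint="auto")
        # the line starts at lateral 0.25 mm: entry face is lateral_min
        assert axis.tip_mm[0] > axis.entry_mm[0]


class TestNeedlePlane:
    def test_axis_along_lateral_gives_elevational_normal(self):
        axis = NeedleAxis([0, 0, 0], [1.0, 0, 0], np.zeros((0, 3)), np.zeros((0, 3)))
        plane = needle_plane(axis)
        assert np.allclose(np.abs(plane.normal), [0, 0, 1.0])
        assert not plane.degenerate

    def test_axis_in_lateral_axial_plane_stays_there(self):
        d = np.array([0.8, 0.6, 0.0])
        axis = NeedleAxis([1, 2, 3], d, np.zeros((0, 3)), np.zeros((0, 3)))
        plane = needle_plane(axis)
        assert np.allclose(np.abs(plane.normal), [0, 0, 1.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_plane_contains_axis_and_is_coronal_perpendicular(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        if abs(d @ AXIAL_UNIT) > 0.99:
            d = np.array([0.5, 0.5, np.sqrt(0.5)])
        p = rng.uniform(-10, 10, size=3)
        axis = NeedleAxis(p, d, np.zeros((0, 3)), np.zeros((0, 3)))
        plane = needle_plane(axis)
        assert abs(plane.normal @ AXIAL_UNIT) < 1e-9
        for t in (-30.0, 30.0):
            assert abs(plane.signed_distance(p + t * d)) < 1e-9

    def test_axial_axis_is_degenerate_fallback(self):
        axis = NeedleAxis([0, 0, 0], [0, 1.0, 0], np.zeros((0, 3)), np.zeros((0, 3)))
        plane = needle_plane(axis)
        assert plane.degenerate
        assert np.allclose(plane.normal, [0, 0, 1.0])


class TestRenderInplaneView:
    def _fit(self, truth):
        return designate_tip(ransac_fit(truth.mask, RansacConfig(seed=0)))

    def test_needle_track_brighter_than_volume_mean(self, easy_phantom):
        vol, truth = easy_phantom
        view = render_inplane_view(vol, self._fit(truth))
        a, b = view.overlay["axis_endpoints_px"]
        n = 30
        rows = np.linspace(a[0], b[0], n).round().astype(int)
        cols = np.linspace(a[1], b[1], n).round().astype(int)
        ok = (rows >= 0) & (rows < view.image.shape[0]) & \
             (cols >= 0) & (cols < view.image.shape[1])
        track = view.image[rows[ok], cols[ok]]
        assert track.mean() > vol.intensities.mean()

    def test_overlay_endpoints_invert_to_axis_endpoints(self, easy_phantom):
        vol, truth = easy_phantom
        fit = self._fit(truth)
        view = render_inplane_view(vol, fit)
        for px, mm in zip(view.overlay["axis_endpoints_px"],
                          view.overlay["axis_endpoints_mm"]):
            back = view.pixel_to_world(np.asarray(px))
            assert np.linalg.norm(back - np.asarray(mm)) < view.sample_step_mm

    def test_constant_volume_renders_with_overlay(self):
        v = UltrasoundVolume(np.full((20, 20, 20), 2.0), 0.5)
        axis = NeedleAxis([2, 2, 2], np.array([0.8, 0.6, 0.0]),
                          np.zeros((0, 3)),
                          np.array([[2.0, 2, 2], [6, 5, 2]]),
                          bounds_mm=(np.zeros(3), np.full(3, 10.0)))
        view = render_inplane_view(v, axis)
        inside = view.image[view.image > 0]
        assert np.allclose(inside, 2.0, atol=1e-6)
        assert "axis_endpoints_px" in view.overlay


class TestPhantomRecovery:
    def test_truth_masks_recover_axis_with_subvoxel_tip_error(self):
        # noise-free detections: RANSAC + plane must be near-exact
        from usneedle.evaluation import orientation_error, tip_error

        rng = np.random.default_rng(0)
        for trial in range(10):
            cfg = PhantomConfig(
                shape=(48, 48, 48), voxel_size_mm=0.2, needle_length_mm=7.0,
                steepness_angle_deg=float(rng.uniform(10, 30)),
                horizontal_angle_deg=float(rng.uniform(-20, 20)),
                n_distractors=0, seed=int(rng.integers(2**31)),
            )
            _, truth = generate_phantom(cfg)
            axis = ransac_fit(truth.mask, RansacConfig(seed=trial))
            assert axis is not None
            axis = designate_tip(axis)
            ev = orientation_error(axis.direction, truth.axis_direction)
            et = tip_error(truth.tip_mm, needle_plane(axis))
            assert ev < 0.5
            assert et < cfg.voxel_size_mm
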