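"""Synthetic generator: exact ground truth, determinism, scene rules."""

import numpy as np
import pytest

from shredmetric.io_model import heightmap_to_cloud
from shredmetric.synthetic import (
    COUNT_TO_MM,
    FilamentSpec,
    GaugeBlockSpec,
    SceneSpec,
    generate_filament,
    generate_gauge_block,
    generate_scene,
    toy_segmentation_scenes,
    _centerline,
)


class TestGaugeBlock:
    def test_surface_difference_is_thickness_on_footprint(self):
        up, lo, truth = generate_gauge_block()
        diff = (up.values - lo.values) * COUNT_TO_MM
        on_block = np.isclose(diff, truth["thickness"], atol=1e-9)
        off_block = np.isclose(diff, 0.0, atol=1e-9)
        assert np.all(on_block | off_block)
        assert on_block.any()

    def test_footprint_pixel_count_matches_grid_enumeration(self):
        pitch = 0.05
        up, lo, truth = generate_gauge_block(pitch=pitch)
        stage_counts = (26.5 + truth["thickness"]) / COUNT_TO_MM
        n_block = int(np.isclose(up.values, stage_counts).sum())
        expected = (30.0 / pitch + 1) * (9.0 / pitch + 1)  # inclusive grid lines
        boundary = 2 * (30.0 / pitch + 9.0 / pitch + 2)
        assert abs(n_block - expected) <= boundary

    def test_fixed_seed_bitwise_identical(self):
        a = generate_gauge_block(sigma_z=0.001, rng_seed=5)[0]
        b = generate_gauge_block(sigma_z=0.001, rng_seed=5)[0]
        np.testing.assert_array_equal(a.values, b.values)

    def test_heightmap_converts_to_cloud(self):
        up, _, _ = generate_gauge_block()
        cloud = heightmap_to_cloud(up, COUNT_TO_MM)
        assert len(cloud) == up.values.size

    def test_bad_dimensions_rejected(self):
        with pytest.raises(ValueError):
            GaugeBlockSpec(thickness=0.0)


class TestFilament:
    def test_zero_curvature_truth_is_straight_length(self):
        spec = FilamentSpec(arc_length=20.0, kind="arc", radius=1e6)
        pts, tans = _centerline(spec, 0.01)
        chord = np.linalg.norm(pts[-1] - pts[0])
        assert chord == pytest.approx(20.0, rel=1e-6)

    def test_arc_closed_form_matches_quadrature(self):
        spec = FilamentSpec(arc_length=20.0, kind="arc", radius=12.0)
        pts, _ = _centerline(spec, 0.005)
        polyline = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert polyline == pytest.approx(20.0, rel=1e-5)
        # endpoint matches r*phi geometry
        phi = 20.0 / 12.0
        chord = np.linalg.norm(pts[-1] - pts[0])
        assert chord == pytest.approx(2 * 12.0 * np.sin(phi / 2), rel=1e-5)

    def test_sine_centerline_has_requested_arc_length(self):
        spec = FilamentSpec(arc_length=25.0, kind="sine", amplitude=1.5, wavelength=12.0)
        pts, _ = _centerline(spec, 0.005)
        polyline = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert polyline == pytest.approx(25.0, rel=1e-4)

    def test_flat_ribbon_has_no_upper_z_spread(self):
        scene = SceneSpec(gauge=None, sigma_z=0.0, sigma_x=0.0)
        spec = FilamentSpec(arc_length=15.0, tilt_deg=0.0)
        upts, lpts, truth = generate_filament(spec, scene)
        # top face is flat; only the thin side faces deviate
        top = np.percentile(upts[:, 2], 60)
        assert upts[:, 2].max() - top < 1e-9
        assert truth["arc_length"] == 15.0

    def test_upper_minus_lower_is_thickness_for_flat_ribbon(self):
        scene = SceneSpec(gauge=None, sigma_z=0.0, sigma_x=0.0)
        spec = FilamentSpec(arc_length=10.0, tilt_deg=0.0, thickness=0.12)
        upts, lpts, _ = generate_filament(spec, scene)
        assert upts[:, 2].max() - lpts[:, 2].min() == pytest.approx(0.12, abs=1e-9)

    def test_self_intersecting_arc_rejected(self):
        with pytest.raises(ValueError):
            FilamentSpec(arc_length=40.0, kind="arc", radius=3.0)


class TestScene:
    def test_label_set_and_truth_rows(self):
        spec = SceneSpec(
            filaments=[
                FilamentSpec(arc_length=10.0, class_label=1, start=(2.0, 2.0)),
                FilamentSpec(arc_length=10.0, class_label=3, start=(10.0, 2.0)),
            ],
            gauge=GaugeBlockSpec(center=(25.0, 8.0), angle_deg=90.0),
            rng_seed=0,
        )
        upper, lower, truth = generate_scene(spec)
        assert set(np.unique(upper.labels)) == {1, 3, 4}
        assert set(np.unique(lower.labels)) == {1, 3, 4}
        assert len(truth.objects) == 3  # gauge + two filaments

    def test_overlapping_objects_rejected(self):
        spec = SceneSpec(
            filaments=[],
            gauge=GaugeBlockSpec(center=(5.0, 5.0)),
            slabs=[GaugeBlockSpec(center=(6.0, 5.0), label=1)],
        )
        with pytest.raises(ValueError, match="overlap"):
            generate_scene(spec)

    def test_deterministic_given_seed(self):
        spec = SceneSpec(
            filaments=[FilamentSpec(arc_length=8.0, class_label=2)],
            gauge=None,
            rng_seed=42,
        )
        a = generate_scene(spec)[0]
        b = generate_scene(spec)[0]
        np.testing.assert_array_equal(a.points, b.points)

    def test_lower_frame_calibrated_to_gauge(self, gauge_pair_scene):
        """With no injected offset the gauge reference surfaces coincide
        across the two emitted clouds."""
        spec, (upper, lower, truth) = gauge_pair_scene
        # undo the injected offset; gauge pixels must then coincide in z
        lo = lower.points[truth.lower_object_ids == 0] + truth.lower_offset
        up = upper.points[truth.upper_object_ids == 0]
        assert abs(np.mean(lo[:, 2]) - np.mean(up[:, 2])) < 1e-9


def test_toy_scenes_cover_all_classes():
    scenes = toy_segmentation_scenes(3, 200, seed=1)
    assert len(scenes) == 3
    for sc in scenes:
        assert len(sc) == 200
        assert set(np.unique(sc.labels)) == {0, 1, 2, 3, 4}
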