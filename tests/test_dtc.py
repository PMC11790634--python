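"""DTC measurement core: projection, skeleton, lifting, length, width,
thickness, and the 2-D baseline."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shredmetric.dtc import (
    MeasureConfig,
    SkeletonPolyline,
    extract_skeleton,
    lift_to_3d,
    measure_instance_dimensions,
    measure_length,
    measure_scene,
    measure_thickness,
    measure_width,
    points_to_mask,
    project_to_image,
    projected_length_2d,
)
from shredmetric.io_model import LabeledPointCloud, ShredInstance
from shredmetric.registration import GaugeReference


class TestProjection:
    def _cloud(self, zs):
        pts = np.column_stack([np.arange(len(zs), dtype=float), np.zeros(len(zs)), zs])
        return LabeledPointCloud(pts, np.zeros(len(zs), dtype=int))

    def test_window_endpoints_map_to_0_and_255(self):
        img = project_to_image(self._cloud([26000.0, 28000.0]), (26000, 28000), 1.0)
        assert img.pixels[0, 0] == 0 and img.pixels[0, 1] == 255

    def test_midpoint_rounds_half_up_to_128(self):
        img = project_to_image(self._cloud([27000.0]), (26000, 28000), 1.0)
        assert img.pixels[0, 0] == 128  # 127.5 rounds half-up

    def test_out_of_window_stays_background(self):
        img = project_to_image(self._cloud([20000.0, 27000.0]), (26000, 28000), 1.0)
        assert img.pixels[0, 0] == 0

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            project_to_image(np.empty((0, 3)), (0, 1), 1.0)


def ribbon_mask(width_px=21, height_px=100):
    mask = np.zeros((height_px, width_px + 20), dtype=bool)
    c0 = 10
    mask[:, c0 : c0 + width_px] = True
    return mask, c0 + (width_px - 1) / 2.0


class TestSkeleton:
    def test_straight_ribbon_centers_on_central_column(self):
        mask, center_col = ribbon_mask()
        sk = extract_skeleton(mask, band_height=5)
        assert sk.measurable
        np.testing.assert_allclose(sk.centers[:, 0], center_col, atol=1.0)
        # chained bottom-to-top
        assert np.all(np.diff(sk.centers[:, 1]) > 0)

    def test_two_parallel_ribbons_give_two_centers_per_band(self):
        mask = np.zeros((20, 60), dtype=bool)
        mask[:, 5:15] = True
        mask[:, 40:50] = True
        sk = extract_skeleton(mask, band_height=5)
        assert len(sk.centers) == 8  # 4 bands x 2 runs
        for y in np.unique(sk.centers[:, 1]):
            assert (sk.centers[:, 1] == y).sum() == 2

    def test_shuffled_collinear_centers_chain_in_order(self):
        """Greedy chaining visits collinear band centers in coordinate
        order regardless of construction order."""
        ys = np.arange(10, dtype=float)
        centers = np.column_stack([np.full(10, 3.0), ys, np.zeros(10)])
        rng = np.random.default_rng(4)
        from shredmetric.dtc import _chain_centers

        chained = _chain_centers(centers[rng.permutation(10)])
        np.testing.assert_allclose(chained[:, 1], ys)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_skeleton(np.zeros((5, 5), dtype=bool), 2)

    def test_single_center_flagged_degenerate(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        sk = extract_skeleton(mask, band_height=5)
        assert not sk.measurable


class TestLift:
    def test_exact_hit_returns_that_z(self):
        cloud = np.array([[0.0, 0, 5.0], [1.0, 0, 7.0], [2.0, 1.0, 9.0], [3.0, 2.0, 1.0]])
        out, mapped = lift_to_3d([[1.0, 0.0]], cloud)
        assert out[0, 2] == pytest.approx(7.0)
        assert mapped.all()

    def test_symmetric_midpoint_averages(self):
        cloud = np.array([[0.0, 0, 1.0], [2.0, 0, 3.0]])
        out, _ = lift_to_3d([[1.0, 0.0]], cloud, m=2)
        assert out[0, 2] == pytest.approx(2.0)

    def test_planar_cloud_maps_to_plane(self, rng):
        cloud = np.column_stack([rng.uniform(0, 1, (50, 2)), np.full(50, 4.2)])
        out, _ = lift_to_3d(rng.uniform(0, 1, (10, 2)), cloud)
        np.testing.assert_allclose(out[:, 2], 4.2)

    def test_cutoff_flags_unmapped(self):
        cloud = np.array([[0.0, 0.0, 1.0]])
        _, mapped = lift_to_3d([[5.0, 5.0]], cloud, cutoff=0.5)
        assert not mapped[0]


class TestLength:
    def test_3_4_5_triangle(self):
        sk = SkeletonPolyline(np.array([[0.0, 0, 0], [3.0, 4.0, 0]]))
        assert measure_length(sk) == pytest.approx(5.0)

    def test_semicircle_converges_to_pi_r(self):
        r = 5.0
        t = np.linspace(0, np.pi, 200)
        centers = np.column_stack([r * np.cos(t), np.zeros(200), r * np.sin(t)])
        sk = SkeletonPolyline(centers)
        assert measure_length(sk) == pytest.approx(np.pi * r, rel=1e-3)

    def test_rigid_rotation_invariance(self, rng):
        centers = rng.normal(0, 2, (20, 3))
        sk = SkeletonPolyline(centers)
        base = measure_length(sk)
        theta = 0.83
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        assert measure_length(SkeletonPolyline(centers @ R.T)) == pytest.approx(
            base, abs=1e-9
        )


class TestProjectedBaseline:
    def test_planar_skeleton_equals_3d(self, rng):
        xy = rng.normal(0, 2, (10, 2))
        centers = np.column_stack([xy, np.full(10, 3.0)])
        sk = SkeletonPolyline(centers)
        assert projected_length_2d(sk) == pytest.approx(measure_length(sk))

    def test_pythagorean_triple(self):
        sk = SkeletonPolyline(np.array([[0.0, 0, 0], [3.0, 4.0, 12.0]]))
        assert projected_length_2d(sk) == pytest.approx(5.0)
        assert measure_length(sk) == pytest.approx(13.0)

    @given(seed=st.integers(0, 500))
    def test_projection_never_longer(self, seed):
        rng = np.random.default_rng(seed)
        sk = SkeletonPolyline(rng.normal(0, 1, (8, 3)))
        assert projected_length_2d(sk) <= measure_length(sk) + 1e-12


class TestWidth:
    def _flat_ribbon(self, width=9.0, length=30.0, pitch=0.05, z=1.0):
        xs = np.arange(0.0, width + pitch / 2, pitch)
        ys = np.arange(0.0, length + pitch / 2, pitch)
        X, Y = np.meshgrid(xs, ys)
        return np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z)])

    def test_flat_ribbon_recovers_width(self):
        pts = self._flat_ribbon()
        cfg = MeasureConfig()
        _, wa, wm, _, _, flags = measure_instance_dimensions(pts, cfg)
        assert wa == pytest.approx(9.0, rel=0.02)
        assert wm == pytest.approx(9.0, rel=0.02)
        assert not flags

    def test_max_at_least_mean(self):
        pts = self._flat_ribbon(width=2.0, length=10.0)
        _, wa, wm, _, _, _ = measure_instance_dimensions(pts, MeasureConfig())
        assert wm >= wa

    def test_tilted_ribbon_true_width_vs_projection(self):
        """A ribbon tilted 60 deg about its long axis projects to half
        its width; the lifted 3-D width recovers the true value."""
        from shredmetric.synthetic import FilamentSpec, SceneSpec, generate_filament

        scene = SceneSpec(gauge=None, sigma_z=0.0, sigma_x=0.0)
        spec = FilamentSpec(
            arc_length=20.0, width=9.0, thickness=0.05, kind="arc", radius=1e5,
            tilt_deg=60.0,
        )
        upts, _, _ = generate_filament(spec, scene)
        _, wa, _, _, _, _ = measure_instance_dimensions(upts, MeasureConfig())
        footprint = upts[:, 0].max() - upts[:, 0].min()
        assert footprint == pytest.approx(4.5, abs=0.2)  # cos 60 foreshortening
        assert wa == pytest.approx(9.0, rel=0.04)


class TestThickness:
    def _gauge(self, top=1.0, thickness=0.5):
        upper = np.column_stack([np.arange(5.0), np.zeros(5), np.full(5, top)])
        lower = upper.copy()  # registered frame: surfaces coincide on the gauge
        return GaugeReference(upper, lower, thickness=thickness)

    def _instance(self, up_z, lo_z):
        up = np.column_stack([np.arange(10.0), np.zeros(10), np.full(10, up_z)])
        lo = np.column_stack([np.arange(10.0), np.zeros(10), np.full(10, lo_z)])
        return ShredInstance(1, up, lo)

    def test_coincident_surfaces_return_gauge_thickness(self):
        t, case = measure_thickness(self._instance(1.0, 1.0), self._gauge())
        assert t == pytest.approx(0.5)
        assert case == "below"

    def test_shred_below_gauge_top(self):
        # upper 0.10 below gauge top, lower 0.05 above gauge bottom ref
        t, case = measure_thickness(self._instance(0.9, 1.05), self._gauge())
        assert t == pytest.approx(0.5 - 0.10 - 0.05)
        assert case == "below"

    def test_shred_above_gauge_top(self):
        t, case = measure_thickness(self._instance(1.1, 1.05), self._gauge())
        assert t == pytest.approx(0.5 + 0.10 - 0.05)
        assert case == "above"

    def test_missing_lower_surface_rejected(self):
        inst = ShredInstance(1, np.zeros((3, 3)))
        with pytest.raises(ValueError):
            measure_thickness(inst, self._gauge())


class TestMeasureScene:
    def test_gauge_only_scene_yields_no_measurements(self, gauge_pair_scene):
        spec, (upper, lower, truth) = gauge_pair_scene
        gauge_only = upper.select(truth.upper_object_ids == 0)
        results = measure_scene(gauge_only, gauge_only, None, MeasureConfig())
        assert results == []

    def test_two_filaments_give_two_records(self):
        from shredmetric.synthetic import FilamentSpec, SceneSpec, generate_scene

        spec = SceneSpec(
            filaments=[
                FilamentSpec(arc_length=12.0, class_label=1, start=(2.0, 2.0)),
                FilamentSpec(arc_length=12.0, class_label=2, start=(10.0, 2.0)),
            ],
            gauge=None,
            sigma_z=0.0,
            sigma_x=0.0,
            rng_seed=0,
        )
        upper, lower, _ = generate_scene(spec)
        results = measure_scene(upper, lower, None, MeasureConfig())
        assert len(results) == 2
        assert sorted(m.class_label for m in results) == [1, 2]
        for m in results:
            assert m.length_mm == pytest.approx(12.0, rel=0.02)
            assert "no_gauge_reference" in m.flags

    def test_translation_invariance(self):
        from shredmetric.synthetic import FilamentSpec, SceneSpec, generate_scene

        spec = SceneSpec(
            filaments=[FilamentSpec(arc_length=10.0, class_label=1)],
            gauge=None, sigma_z=0.0, sigma_x=0.0, rng_seed=0,
        )
        upper, lower, _ = generate_scene(spec)
        base = measure_scene(upper, lower, None, MeasureConfig())[0]
        shift = np.array([7.3, -2.1, 0.4])
        moved = measure_scene(
            upper.translated(shift), lower.translated(shift), None, MeasureConfig()
        )[0]
        assert moved.length_mm == pytest.approx(base.length_mm, rel=0.02)
        assert moved.width_avg_mm == pytest.approx(base.width_avg_mm, rel=0.02)
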