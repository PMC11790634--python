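"""Desk-scale validation experiments with known ground truth.

These runs exercise the full measurement chain on synthetic scans whose
dimensions are exact by construction:

* :func:`gauge_dimension_run` — length and average width of the
  noiseless reference gauge block (30 × 9 mm nominal footprint);
* :func:`filament_noise_run` — relative length/width errors over a set
  of curved, tilted filaments with sensor-scale Gaussian noise;
* :func:`thickness_validation_run` — gauge-referenced thickness of a
  slab of known thickness after dual-surface registration, with height
  noise.

Each function is deterministic given its seed(s) and returns plain
floats, so they serve equally as regression checks and as the
reproduction entry points documented in the README.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dtc import MeasureConfig, measure_instance_dimensions, measure_thickness
from .io_model import ShredInstance, heightmap_to_cloud
from .registration import extract_reference_points, register_lower
from .synthetic import (
    COUNT_TO_MM,
    DEFAULT_PITCH,
    DEFAULT_SIGMA_X,
    DEFAULT_SIGMA_Z,
    HEIGHT_WINDOW_MM,
    FilamentSpec,
    GaugeBlockSpec,
    SceneSpec,
    generate_filament,
    generate_gauge_block,
    generate_scene,
)


def gauge_dimension_run(
    pitch: float = DEFAULT_PITCH, band_height: int = 5, rng_seed: int = 0
) -> tuple[float, float, float]:
    """Measure the noiseless reference gauge block's footprint.

    Generates the dual-surface scan of the standard block, converts the
    upper height map to a cloud, and runs the projection → skeleton →
    lift → length/width chain on the block surface.  Returns
    ``(length_mm, width_avg_mm, width_max_mm)``.
    """
    upper_hm, _, _ = generate_gauge_block(pitch=pitch, rng_seed=rng_seed)
    cloud = heightmap_to_cloud(upper_hm, COUNT_TO_MM)
    lo, hi = HEIGHT_WINDOW_MM
    on_block = (cloud.points[:, 2] >= lo) & (cloud.points[:, 2] <= hi)
    cfg = MeasureConfig(pixel_to_mm=pitch, band_height=band_height)
    length, wa, wm, _, _, flags = measure_instance_dimensions(
        cloud.points[on_block], cfg
    )
    if flags:
        raise RuntimeError(f"gauge measurement flagged: {flags}")
    return length, wa, wm


@dataclass
class FilamentRunResult:
    lengths_true: np.ndarray
    lengths_measured: np.ndarray
    widths_true: np.ndarray
    widths_measured: np.ndarray

    @property
    def max_length_error_pct(self) -> float:
        return float(
            (np.abs(self.lengths_measured - self.lengths_true) / self.lengths_true).max()
            * 100.0
        )

    @property
    def max_width_error_pct(self) -> float:
        return float(
            (np.abs(self.widths_measured - self.widths_true) / self.widths_true).max()
            * 100.0
        )


def _draw_filament(i: int, rng: np.random.Generator) -> FilamentSpec:
    """One filament under the validation conditions: arc length
    10-40 mm, width 0.8-1.2 mm, tilt up to 45 deg, alternating
    circular-arc and sinusoidal centerlines."""
    arc_length = float(rng.uniform(10.0, 40.0))
    width = float(rng.uniform(0.8, 1.2))
    tilt = float(rng.uniform(0.0, 45.0))
    if i % 2 == 0:
        phi = float(rng.uniform(0.5, 1.8))  # subtended angle, rad
        return FilamentSpec(
            arc_length=arc_length, width=width, kind="arc",
            radius=arc_length / phi, tilt_deg=tilt, class_label=i % 4,
        )
    return FilamentSpec(
        arc_length=arc_length, width=width, kind="sine",
        amplitude=float(rng.uniform(0.8, 1.6)),
        wavelength=float(rng.uniform(10.0, 20.0)),
        tilt_deg=tilt, class_label=i % 4,
    )


def filament_noise_run(
    seeds: list[int],
    pitch: float = DEFAULT_PITCH,
    sigma_z: float = DEFAULT_SIGMA_Z,
    sigma_x: float = DEFAULT_SIGMA_X,
    band_height: int = 5,
) -> FilamentRunResult:
    """Measure one noisy filament per seed and collect errors against
    the generator's exact dimensions."""
    cfg = MeasureConfig(pixel_to_mm=pitch, band_height=band_height)
    lt, lm, wt, wm_ = [], [], [], []
    for i, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        spec = _draw_filament(i, rng)
        scene = SceneSpec(
            gauge=None, pitch=pitch, sigma_z=sigma_z, sigma_x=sigma_x, rng_seed=seed
        )
        upper_pts, _, truth = generate_filament(spec, scene, rng=rng)
        length, wa, _, _, _, flags = measure_instance_dimensions(upper_pts, cfg)
        if flags:
            raise RuntimeError(f"filament {i} (seed {seed}) flagged: {flags}")
        lt.append(truth["arc_length"])
        lm.append(length)
        wt.append(truth["width"])
        wm_.append(wa)
    return FilamentRunResult(
        np.asarray(lt), np.asarray(lm), np.asarray(wt), np.asarray(wm_)
    )


def _thickness_scene(seed: int, sigma_z: float, slab_thickness: float) -> SceneSpec:
    return SceneSpec(
        gauge=GaugeBlockSpec(center=(5.0, 16.0), angle_deg=90.0),
        slabs=[
            GaugeBlockSpec(
                center=(17.0, 16.0), angle_deg=90.0,
                thickness=slab_thickness, label=1,
            )
        ],
        filaments=[],
        sigma_z=sigma_z,
        sigma_x=0.0,
        lower_offset=(0.3, -0.2, 0.1),
        rng_seed=seed,
    )


def measure_slab_thickness(
    seed: int, sigma_z: float = 0.0, slab_thickness: float = 0.5
) -> tuple[float, float]:
    """Generate gauge + slab, register the surfaces, and return
    ``(measured_thickness, true_thickness)``."""
    spec = _thickness_scene(seed, sigma_z, slab_thickness)
    upper, lower, truth = generate_scene(spec)
    up_gauge = upper.select(truth.upper_object_ids == 0)
    lo_gauge = lower.select(truth.lower_object_ids == 0)
    ref = extract_reference_points(up_gauge, lo_gauge, thickness=spec.gauge.thickness)
    lower_reg, _ = register_lower(lower, ref)
    ref_reg = ref.registered()
    slab = ShredInstance(
        1,
        upper.points[truth.upper_object_ids == 1],
        lower_reg.points[truth.lower_object_ids == 1],
    )
    measured, _ = measure_thickness(slab, ref_reg)
    return measured, slab_thickness


def thickness_validation_run(
    seeds: list[int], sigma_z: float = DEFAULT_SIGMA_Z, slab_thickness: float = 0.5
) -> float:
    """Mean relative thickness error (percent) over seeded repeats of
    the noisy slab-versus-gauge validation."""
    errs = []
    for seed in seeds:
        measured, true = measure_slab_thickness(seed, sigma_z, slab_thickness)
        errs.append(abs(measured - true) / true)
    return float(np.mean(errs) * 100.0)
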