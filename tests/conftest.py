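import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from shredmetric.io_model import LabeledPointCloud

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cloud(rng):
    """200 generic points with mixed labels."""
    pts = rng.uniform(-5.0, 5.0, (200, 3))
    labels = rng.integers(0, 5, 200)
    return LabeledPointCloud(pts, labels)


@pytest.fixture(scope="session")
def gauge_pair_scene():
    """Noiseless scene: reference gauge plus an identical-thickness slab,
    with an injected lower-surface misalignment."""
    from shredmetric.synthetic import GaugeBlockSpec, SceneSpec, generate_scene

    spec = SceneSpec(
        gauge=GaugeBlockSpec(center=(5.0, 16.0), angle_deg=90.0),
        slabs=[GaugeBlockSpec(center=(17.0, 16.0), angle_deg=90.0, thickness=0.5, label=1)],
        filaments=[],
        sigma_z=0.0,
        sigma_x=0.0,
        lower_offset=(0.3, -0.2, 0.1),
        rng_seed=1,
    )
    return spec, generate_scene(spec)
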