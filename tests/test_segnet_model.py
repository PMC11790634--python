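"""Network training and prediction: bookkeeping, determinism, gradient
correctness, and permutation equivariance."""

import numpy as np
import pytest

from shredmetric.io_model import LabeledPointCloud
from shredmetric.segnet import (
    NetworkConfig,
    PointSegNet,
    build_and_train,
    cosine_annealing_lr,
    predict_labels,
)
from shredmetric.segnet import autograd as ag
from shredmetric.synthetic import toy_segmentation_scenes


def desk_config(**overrides):
    base = dict(
        n_input_points=128,
        centroids_per_level=(32, 8),
        k_lists=((4, 8), (4,)),
        splice_combo="R1-2-R2-1",
        sa_widths=((16, 16), (32, 32)),
        fp_widths=((32,), (16,)),
        head_widths=(16,),
        epochs=2,
        batch_size=4,
        eta_max=5e-3,
        eta_min=1e-4,
        rng_seed=0,
    )
    base.update(overrides)
    return NetworkConfig(**base)


class TestConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            desk_config(centroids_per_level=(8, 32))
        with pytest.raises(ValueError):
            desk_config(eta_max=1e-5, eta_min=1e-3)
        with pytest.raises(ValueError):
            desk_config(class_weights=(1, 1, 0, 1, 1))
        with pytest.raises(ValueError):
            desk_config(splice_combo="R-banana")

    def test_splice_combo_selects_k_prefixes(self):
        cfg = NetworkConfig(splice_combo="R1-2-R2-1")
        assert cfg.level_ks() == [[16, 32], [16]]
        cfg = NetworkConfig(splice_combo="R1-3-R2-2")
        assert cfg.level_ks() == [[16, 32, 48], [16, 32]]


class TestAutogradGradients:
    def test_matches_finite_differences(self):
        """End-to-end gradient of a small network loss vs central
        finite differences on a few parameters."""
        rng = np.random.default_rng(0)
        model = PointSegNet(desk_config())
        pts = rng.normal(0, 1, (32, 3))
        labels = rng.integers(0, 5, 32)
        weights = np.ones(5)

        def loss_value():
            logits = model.forward(pts)
            return float(
                ag.weighted_nll(ag.log_softmax(logits), labels, weights).data
            )

        logits = model.forward(pts)
        loss = ag.weighted_nll(ag.log_softmax(logits), labels, weights)
        loss.backward()
        target = model.params[0]
        analytic = target.grad.copy()
        eps = 1e-6
        for idx in [(0, 0), (1, 2), (3, 1)]:
            orig = target.data[idx]
            target.data[idx] = orig + eps
            up = loss_value()
            target.data[idx] = orig - eps
            down = loss_value()
            target.data[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert analytic[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)


class TestTraining:
    def test_two_epoch_bookkeeping(self):
        scenes = toy_segmentation_scenes(4, 128, seed=1)
        cfg = desk_config(epochs=2)
        _, history = build_and_train(scenes, cfg)
        assert len(history["loss"]) == 2 and len(history["lr"]) == 2
        for epoch, lr in enumerate(history["lr"]):
            assert lr == pytest.approx(
                cosine_annealing_lr(epoch, cfg.epochs, cfg.eta_min, cfg.eta_max)
            )

    def test_loss_decreases_on_separable_scenes(self):
        scenes = toy_segmentation_scenes(4, 128, seed=2)
        _, history = build_and_train(scenes, desk_config(epochs=10))
        assert history["loss"][-1] < history["loss"][0]

    def test_training_is_deterministic(self):
        scenes = toy_segmentation_scenes(2, 128, seed=3)
        test = toy_segmentation_scenes(1, 128, seed=9)[0]
        m1, h1 = build_and_train(scenes, desk_config(epochs=2))
        m2, h2 = build_and_train(scenes, desk_config(epochs=2))
        assert h1["loss"] == h2["loss"]
        np.testing.assert_array_equal(m1.predict(test.points), m2.predict(test.points))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            build_and_train([], desk_config())


@pytest.fixture(scope="module")
def trained():
    scenes = toy_segmentation_scenes(4, 128, seed=4)
    model, _ = build_and_train(scenes, desk_config(epochs=5))
    return model


class TestPrediction:
    def test_labels_valid_and_coords_untouched(self, trained):
        cloud = toy_segmentation_scenes(1, 100, seed=10)[0]
        pred = predict_labels(trained, cloud)
        assert set(np.unique(pred.labels)) <= set(range(5))
        np.testing.assert_array_equal(pred.points, cloud.points)

    def test_argmax_matches_manual_oracle(self, trained):
        from shredmetric.segnet import normalize_points

        cloud = toy_segmentation_scenes(1, 90, seed=11)[0]
        pred = trained.predict(cloud.points)
        norm, _, _ = normalize_points(cloud.points)
        logits = trained.forward(norm).data
        np.testing.assert_array_equal(pred, np.argmax(logits, axis=1))

    def test_repeated_prediction_identical(self, trained):
        cloud = toy_segmentation_scenes(1, 80, seed=12)[0]
        a = trained.predict(cloud.points)
        b = trained.predict(cloud.points)
        np.testing.assert_array_equal(a, b)

    def test_permutation_equivariance(self, trained):
        cloud = toy_segmentation_scenes(1, 80, seed=13)[0]
        perm = np.random.default_rng(0).permutation(len(cloud))
        base = trained.predict(cloud.points)
        permuted = trained.predict(cloud.points[perm])
        np.testing.assert_array_equal(permuted, base[perm])

    def test_empty_input_rejected(self, trained):
        with pytest.raises(ValueError):
            trained.predict(np.empty((0, 3)))


def test_model_save_load_round_trip(tmp_path):
    scenes = toy_segmentation_scenes(2, 128, seed=5)
    model, _ = build_and_train(scenes, desk_config(epochs=1))
    model.save(tmp_path / "model")
    back = PointSegNet.load(tmp_path / "model")
    cloud = toy_segmentation_scenes(1, 64, seed=6)[0]
    np.testing.assert_array_equal(back.predict(cloud.points), model.predict(cloud.points))
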