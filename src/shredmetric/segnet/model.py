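"""Hierarchical point-cloud segmentation network.

The architecture follows the set-abstraction / feature-propagation
design for per-point semantic labelling, with three modifications that
matter for thin filamentous material:

* grouping is KNN-based and *multi-scale* — each abstraction level
  gathers every centroid's neighbourhood at several k values and
  concatenates the pooled features, instead of a single radius ball
  query;
* the loss is class-weighted cross-entropy (background points vastly
  outnumber shred points);
* the learning rate follows a cosine-annealing schedule.

Two set-abstraction levels (default 512 then 128 centroids chosen by
farthest point sampling) encode the cloud; two feature-propagation
levels interpolate back to full resolution with inverse-distance
weights over 3 neighbours; a shared per-point head emits 5-class
logits.  Everything runs on NumPy via the small autodiff core in
:mod:`shredmetric.segnet.autograd`.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ..io_model import LabeledPointCloud
from . import autograd as ag
from .losses import cosine_annealing_lr
from .sampling import farthest_point_sample, knn_group

log = logging.getLogger(__name__)

_COMBO_RE = re.compile(r"^R1-(\d+)-R2-(\d+)$")


@dataclass
class NetworkConfig:
    """Architecture and training hyper-parameters.

    ``k_lists`` holds the ordered candidate k values per abstraction
    level; ``splice_combo`` of the form ``"R1-a-R2-b"`` selects the
    first ``a`` entries for level 1 and the first ``b`` for level 2.
    The default combo R1-2-R2-1 therefore groups at k = {16, 32} on the
    first level and k = {16} on the second.
    """

    n_input_points: int = 4096
    centroids_per_level: tuple[int, int] = (512, 128)
    k_lists: tuple[tuple[int, ...], ...] = (
        (16, 32, 48, 64, 80, 96, 112),
        (16, 32, 48, 64, 80, 96, 112),
    )
    splice_combo: str = "R1-2-R2-1"
    class_weights: tuple[float, ...] = (4.0, 4.0, 4.0, 4.0, 1.0)
    eta_min: float = 1e-5
    eta_max: float = 1e-3
    T_restart: int | None = None  # None -> single period spanning all epochs
    epochs: int = 150
    batch_size: int = 16
    rng_seed: int = 0
    sa_widths: tuple[tuple[int, ...], ...] = ((64, 64), (128, 128))
    fp_widths: tuple[tuple[int, ...], ...] = ((128,), (64,))
    head_widths: tuple[int, ...] = (64,)
    n_classes: int = 5

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.centroids_per_level, self.centroids_per_level[1:])):
            raise ValueError("centroid counts must be strictly decreasing")
        if any(k < 1 for ks in self.k_lists for k in ks):
            raise ValueError("all k values must be >= 1")
        if not self.eta_min < self.eta_max:
            raise ValueError("eta_min must be < eta_max")
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be > 0")
        if not _COMBO_RE.match(self.splice_combo):
            raise ValueError("splice_combo must look like 'R1-2-R2-1'")

    def level_ks(self) -> list[list[int]]:
        """k values actually used per level, per the splice combo."""
        a, b = (int(g) for g in _COMBO_RE.match(self.splice_combo).groups())
        picks = []
        for level, n in enumerate((a, b)):
            ks = self.k_lists[level]
            if not 1 <= n <= len(ks):
                raise ValueError(
                    f"splice index {n} out of range for level {level + 1} k list {ks}"
                )
            picks.append(list(ks[:n]))
        return picks


def normalize_points(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Center to the centroid and scale to the unit sphere."""
    center = points.mean(axis=0)
    shifted = points - center
    scale = float(np.linalg.norm(shifted, axis=1).max())
    if scale == 0.0:
        scale = 1.0
    return shifted / scale, center, scale


class _MLP:
    """Shared per-point MLP: affine + ReLU stack (optional linear tail)."""

    def __init__(self, dims: list[int], rng: np.random.Generator, final_relu: bool = True):
        self.weights: list[ag.Tensor] = []
        self.biases: list[ag.Tensor] = []
        self.final_relu = final_relu
        for d_in, d_out in zip(dims, dims[1:]):
            w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
            self.weights.append(ag.param(w))
            self.biases.append(ag.param(np.zeros(d_out)))

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        shape = x.shape
        flat = ag.reshape(x, (-1, shape[-1])) if len(shape) > 2 else x
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            flat = ag.add_bias(ag.matmul(flat, w), b)
            if self.final_relu or i < len(self.weights) - 1:
                flat = ag.relu(flat)
        if len(shape) > 2:
            flat = ag.reshape(flat, shape[:-1] + (flat.shape[-1],))
        return flat

    @property
    def params(self) -> list[ag.Tensor]:
        return self.weights + self.biases


class PointSegNet:
    """Encoder-decoder segmentation network over raw xyz input."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        level_ks = config.level_ks()
        self.level_ks = level_ks
        self.sa_mlps: list[list[_MLP]] = []
        c_in = 3  # xyz features
        self.skip_dims = [c_in]
        for level, ks in enumerate(level_ks):
            width = list(config.sa_widths[level])
            mlps = [_MLP([c_in + 3] + width, rng) for _ in ks]
            self.sa_mlps.append(mlps)
            c_in = width[-1] * len(ks)
            self.skip_dims.append(c_in)
        # decoder: coarse -> fine, concatenating skip features
        self.fp_mlps: list[_MLP] = []
        c_coarse = c_in
        for level in range(len(level_ks) - 1, -1, -1):
            c_skip = self.skip_dims[level]
            widths = list(config.fp_widths[len(level_ks) - 1 - level])
            self.fp_mlps.append(_MLP([c_coarse + c_skip] + widths, rng))
            c_coarse = widths[-1]
        self.head = _MLP(
            [c_coarse] + list(config.head_widths) + [config.n_classes], rng, final_relu=False
        )

    @property
    def params(self) -> list[ag.Tensor]:
        out: list[ag.Tensor] = []
        for mlps in self.sa_mlps:
            for m in mlps:
                out.extend(m.params)
        for m in self.fp_mlps:
            out.extend(m.params)
        out.extend(self.head.params)
        return out

    # -- forward ----------------------------------------------------------

    def _set_abstraction(
        self, points: np.ndarray, feats: ag.Tensor, level: int
    ) -> tuple[np.ndarray, ag.Tensor]:
        m = min(self.config.centroids_per_level[level], len(points))
        cent_idx = farthest_point_sample(points, m)
        new_points = points[cent_idx]
        pooled = []
        for k, mlp in zip(self.level_ks[level], self.sa_mlps[level]):
            nidx = knn_group(points, cent_idx, k)
            rel = points[nidx] - new_points[:, None, :]
            grouped = ag.concat([ag.gather_rows(feats, nidx), ag.constant(rel)], axis=-1)
            pooled.append(ag.max_pool_axis(mlp(grouped), axis=1))
        return new_points, ag.concat(pooled, axis=-1)

    @staticmethod
    def _interpolate(
        fine_points: np.ndarray, coarse_points: np.ndarray, coarse_feats: ag.Tensor
    ) -> ag.Tensor:
        """Inverse-distance interpolation over 3 coarse neighbours."""
        k = min(3, len(coarse_points))
        tree = cKDTree(coarse_points)
        d, idx = tree.query(fine_points, k=k)
        d = np.atleast_2d(d).reshape(len(fine_points), k)
        idx = np.atleast_2d(idx).reshape(len(fine_points), k)
        w = 1.0 / (d + 1e-8)
        w /= w.sum(axis=1, keepdims=True)
        return ag.weighted_sum_rows(coarse_feats, idx, w)

    def forward(self, points_norm: np.ndarray) -> ag.Tensor:
        """Per-point logits for a normalized cloud of shape (N, 3)."""
        pts = [np.asarray(points_norm, dtype=np.float64)]
        feats = [ag.constant(pts[0])]
        for level in range(len(self.level_ks)):
            p, f = self._set_abstraction(pts[level], feats[level], level)
            pts.append(p)
            feats.append(f)
        f = feats[-1]
        for i, level in enumerate(range(len(self.level_ks) - 1, -1, -1)):
            interp = self._interpolate(pts[level], pts[level + 1], f)
            f = self.fp_mlps[i](ag.concat([interp, feats[level]], axis=-1))
        return self.head(f)

    def predict(self, points_mm: np.ndarray) -> np.ndarray:
        """Argmax class per point (deterministic)."""
        points_mm = np.asarray(points_mm, dtype=np.float64)
        if len(points_mm) == 0:
            raise ValueError("empty input")
        norm, _, _ = normalize_points(points_mm)
        logits = self.forward(norm)
        return np.argmax(logits.data, axis=1).astype(np.int64)

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": t.data for i, t in enumerate(self.params)}
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "PointSegNet":
        path = Path(path)
        raw = json.loads(path.with_suffix(".json").read_text())
        for key in ("centroids_per_level", "class_weights", "head_widths"):
            raw[key] = tuple(raw[key])
        for key in ("k_lists", "sa_widths", "fp_widths"):
            raw[key] = tuple(tuple(v) for v in raw[key])
        model = cls(NetworkConfig(**raw))
        with np.load(path.with_suffix(".npz")) as data:
            for i, t in enumerate(model.params):
                t.data[...] = data[f"p{i}"]
        return model


class _Adam:
    def __init__(self, params: list[ag.Tensor], beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1 ** self.t)
            v_hat = v / (1 - self.beta2 ** self.t)
            p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _resample(
    points: np.ndarray, labels: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if len(points) >= n:
        idx = rng.choice(len(points), size=n, replace=False)
    else:
        log.warning("sample has %d < %d points; resampling with replacement",
                    len(points), n)
        idx = rng.choice(len(points), size=n, replace=True)
    return points[idx], labels[idx]


def build_and_train(
    dataset: list[LabeledPointCloud], config: NetworkConfig
) -> tuple[PointSegNet, dict]:
    """Train a :class:`PointSegNet` on labeled clouds.

    Each sample is randomly resampled to ``config.n_input_points``,
    normalized to the unit sphere, and fed through the network; the
    class-weighted cross-entropy gradient is accumulated per batch and
    applied with Adam at the cosine-annealed rate for the epoch.
    Deterministic given ``config.rng_seed``.

    Returns the trained model and a history dict with per-epoch mean
    loss and learning rate.
    """
    if not dataset:
        raise ValueError("dataset must be nonempty")
    model = PointSegNet(config)
    rng = np.random.default_rng(config.rng_seed + 1)
    opt = _Adam(model.params)
    weights = np.asarray(config.class_weights, dtype=np.float64)
    t_restart = config.T_restart or config.epochs
    history: dict = {"loss": [], "lr": []}
    for epoch in range(config.epochs):
        lr = cosine_annealing_lr(epoch, t_restart, config.eta_min, config.eta_max)
        order = rng.permutation(len(dataset))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            opt.zero_grad()
            for si in batch:
                cloud = dataset[si]
                pts, labels = _resample(cloud.points, cloud.labels, config.n_input_points, rng)
                norm, _, _ = normalize_points(pts)
                logits = model.forward(norm)
                loss = ag.weighted_nll(ag.log_softmax(logits), labels, weights)
                loss.backward()
                epoch_losses.append(float(loss.data))
            # average accumulated gradients over the batch
            for p in model.params:
                if p.grad is not None:
                    p.grad /= len(batch)
            opt.step(lr)
        history["loss"].append(float(np.mean(epoch_losses)))
        history["lr"].append(lr)
        log.debug("epoch %d: loss=%.4f lr=%.2e", epoch, history["loss"][-1], lr)
    return model, history


def predict_labels(model: PointSegNet, cloud: LabeledPointCloud) -> LabeledPointCloud:
    """Predicted per-point classes; coordinates pass through untouched."""
    if len(cloud) == 0:
        raise ValueError("empty input cloud")
    labels = model.predict(cloud.points)
    return LabeledPointCloud(cloud.points.copy(), labels, cloud.surface)
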