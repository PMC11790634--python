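"""Training-side scalar functions: class-weighted cross-entropy and the
cosine-annealing learning-rate schedule (with warm restarts)."""

from __future__ import annotations

import logging
import math

import numpy as np

log = logging.getLogger(__name__)


def weighted_cross_entropy(
    pred_probs: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    eps: float = 1e-12,
) -> float:
    """Class-weighted cross-entropy over a batch of probability rows.

    ``L = -(1/N) * sum_i w[y_i] * log p[i, y_i]`` with natural log.
    Background-dominated point clouds make the unweighted loss neglect
    the minority shred classes; weighting (default elsewhere in this
    package: [4, 4, 4, 4, 1]) rebalances the gradient toward them.

    Rows of ``pred_probs`` must sum to 1 within 1e-6.  Zero probability
    at a true class is clamped at ``eps`` (with a warning) instead of
    producing an infinite loss.
    """
    p = np.asarray(pred_probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64).ravel()
    weights = np.asarray(weights, dtype=np.float64).ravel()
    if p.ndim != 2 or len(labels) != len(p):
        raise ValueError("pred_probs must be (N, C) with labels of length N")
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= p.shape[1]:
        raise ValueError("labels outside 0..C-1")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each probability row must sum to 1 within 1e-6")
    p_true = p[np.arange(len(labels)), labels]
    if (p_true < eps).any():
        log.warning("weighted_cross_entropy: clamping %d zero probabilities at eps=%g",
                    int((p_true < eps).sum()), eps)
        p_true = np.maximum(p_true, eps)
    return float(-(weights[labels] * np.log(p_true)).mean())


def cosine_annealing_lr(
    T_i: int | float, T_restart: int, eta_min: float, eta_max: float
) -> float:
    """Cosine-annealed learning rate with warm restarts every
    ``T_restart`` epochs:

    ``eta = eta_min + (eta_max - eta_min)/2 * (1 + cos(pi * (T_i mod T_restart) / T_restart))``

    so the rate starts at ``eta_max``, decays along a half cosine to
    ``eta_min`` at the period end, then restarts.
    """
    if T_restart < 1:
        raise ValueError("T_restart must be >= 1")
    if eta_min > eta_max:
        raise ValueError("eta_min must be <= eta_max")
    phase = (T_i % T_restart) / T_restart
    return eta_min + 0.5 * (eta_max - eta_min) * (1.0 + math.cos(math.pi * phase))
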