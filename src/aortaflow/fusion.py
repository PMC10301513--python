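"""STAPLE fusion of multiple observers' binary segmentations.

Simultaneous Truth And Performance Level Estimation treats the unknown true
segmentation as a latent binary variable and each rater's mask as a noisy
observation characterised by a sensitivity p_j and specificity q_j.  An EM
iteration alternates a per-voxel posterior truth probability (E-step) with
re-estimation of (p_j, q_j) (M-step).  The prior foreground probability is
spatially uniform, initialised as the mean foreground fraction across raters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import SegmentationMask

logger = logging.getLogger(__name__)

__all__ = ["StapleResult", "staple_fuse"]


@dataclass
class StapleResult:
    probability: np.ndarray
    consensus: SegmentationMask
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_iterations: int
    log_likelihood: list


def staple_fuse(
    masks: list[SegmentationMask],
    max_iter: int = 100,
    tol: float = 1e-6,
) -> StapleResult:
    """Fuse >= 2 binary masks into a probabilistic truth estimate.

    Raters that are all-empty or all-full carry no information about the
    decision boundary and are excluded with a warning.  The consensus mask is
    ``probability >= 0.5`` (ties count as foreground).  The per-iteration
    observed-data log-likelihood is recorded and is non-decreasing.
    """
    shape = masks[0].voxels.shape
    spacing = masks[0].spacing
    usable = []
    for i, m in enumerate(masks):
        if m.voxels.shape != shape:
            raise ValueError(f"mask {i} shape {m.voxels.shape} differs from {shape}")
        if not m.voxels.any() or m.voxels.all():
            logger.warning("rater %d is all-%s; excluded from fusion",
                           i, "full" if m.voxels.any() else "empty")
            continue
        usable.append(m.voxels.ravel().astype(float))
    if len(usable) < 2:
        raise ValueError("need at least 2 usable raters")

    D = np.stack(usable, axis=0)  # (J, V)
    J, V = D.shape
    prior = float(D.mean())
    p = np.full(J, 0.99)  # sensitivities
    q = np.full(J, 0.99)  # specificities

    eps = 1e-12
    ll_trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: posterior probability the voxel is truly foreground
        log_a = np.log(prior + eps) + np.sum(
            D * np.log(p + eps)[:, None] + (1 - D) * np.log(1 - p + eps)[:, None], axis=0
        )
        log_b = np.log(1 - prior + eps) + np.sum(
            (1 - D) * np.log(q + eps)[:, None] + D * np.log(1 - q + eps)[:, None], axis=0
        )
        m = np.maximum(log_a, log_b)
        denom = np.exp(log_a - m) + np.exp(log_b - m)
        W = np.exp(log_a - m) / denom
        ll_trace.append(float(np.sum(m + np.log(denom))))

        # M-step: rater performance given the soft truth
        sum_w = W.sum()
        sum_not_w = V - sum_w
        p_new = (D @ W) / max(sum_w, eps)
        q_new = ((1 - D) @ (1 - W)) / max(sum_not_w, eps)
        change = max(np.max(np.abs(p_new - p)), np.max(np.abs(q_new - q)))
        p, q = p_new, q_new
        if change < tol:
            break

    probability = W.reshape(shape)
    consensus = SegmentationMask(probability >= 0.5, spacing)
    return StapleResult(probability, consensus, p, q, it, ll_trace)
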