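"""Velocity structure tensor and discontinuity function R.

At a vessel wall during a flow jet, two dominant flow directions coexist
within a local neighbourhood (the jet direction and the direction induced by
the wall), while the free lumen has a single dominant direction.  The
Gaussian-weighted outer product of the velocity field,

    M = G_sigma * (v v^T),

captures this: its sorted eigenvalues lambda1 >= lambda2 >= lambda3 rank the
local flow directions, and

    R = 4 lambda1 lambda2 / (lambda1 + lambda2)^2

is 0 for a single dominant direction, 1 for two (or more) equally dominant
directions, and in between otherwise.  R is invariant to rescaling the
velocity field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "StructureTensorField",
    "EigenField",
    "DiscontinuityField",
    "structure_tensor",
    "tensor_eigenvalues",
    "discontinuity_field",
    "compute_discontinuity",
]

#: component ordering of the six unique tensor entries
COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")
_IDX = {"xx": (0, 0), "yy": (1, 1), "zz": (2, 2), "xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}

#: relative clamp tolerance for small negative eigenvalues
EIG_CLAMP_RTOL = 1e-8


@dataclass
class StructureTensorField:
    """Six unique components of the smoothed velocity structure tensor.

    ``components`` has shape (X, Y, Z, 6) ordered (xx, yy, zz, xy, xz, yz),
    units (cm/s)^2; ``sigma`` is the Gaussian scale in voxels.
    """

    components: np.ndarray
    sigma: float

    def as_matrices(self) -> np.ndarray:
        """Full symmetric tensors, shape (X, Y, Z, 3, 3)."""
        c = self.components
        m = np.zeros(c.shape[:3] + (3, 3))
        for k, name in enumerate(COMPONENTS):
            i, j = _IDX[name]
            m[..., i, j] = c[..., k]
            m[..., j, i] = c[..., k]
        return m


@dataclass
class EigenField:
    """Sorted structure-tensor eigenvalues lambda1 >= lambda2 >= lambda3 >= 0."""

    lam1: np.ndarray
    lam2: np.ndarray
    lam3: np.ndarray


@dataclass
class DiscontinuityField:
    """Per-voxel discontinuity function R in [0, 1]."""

    R: np.ndarray


def structure_tensor(velocity_frame: np.ndarray, sigma: float = 1.0) -> StructureTensorField:
    """Gaussian-smoothed outer product of one frame's velocity field.

    ``velocity_frame`` has shape (X, Y, Z, 3) in cm/s; each of the six unique
    product fields is smoothed independently with a Gaussian of scale
    ``sigma`` voxels (reflective boundaries, truncation 4 sigma);
    ``sigma = 0`` applies no smoothing.
    """
    v = np.asarray(velocity_frame, dtype=float)
    if v.ndim != 4 or v.shape[-1] != 3:
        raise ValueError("velocity_frame must have shape (X, Y, Z, 3)")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    comps = np.empty(v.shape[:3] + (6,))
    for k, name in enumerate(COMPONENTS):
        i, j = _IDX[name]
        prod = v[..., i] * v[..., j]
        if sigma > 0:
            prod = gaussian_filter(prod, sigma, mode="reflect", truncate=4.0)
        comps[..., k] = prod
    return StructureTensorField(comps, sigma)


def tensor_eigenvalues(tf: StructureTensorField) -> EigenField:
    """Per-voxel symmetric eigendecomposition, sorted descending.

    Eigenvalues within 1e-8 * lambda1 of zero (either sign: numerical noise
    of the decomposition on rank-deficient tensors) are clamped to zero.
    """
    mats = tf.as_matrices()
    lams = np.linalg.eigvalsh(mats)[..., ::-1]  # descending
    lam1 = lams[..., 0]
    tol = (EIG_CLAMP_RTOL * np.maximum(lam1, 1.0))[..., None]
    lams = np.where(np.abs(lams) <= tol, 0.0, lams)
    return EigenField(lams[..., 0], lams[..., 1], lams[..., 2])


def discontinuity_field(ev: EigenField) -> DiscontinuityField:
    """R = 4 lambda1 lambda2 / (lambda1 + lambda2)^2, with R = 0 when both vanish."""
    lam1 = np.asarray(ev.lam1, dtype=float)
    lam2 = np.asarray(ev.lam2, dtype=float)
    if np.any(lam1 < 0) or np.any(lam2 < 0):
        raise ValueError("eigenvalues must be non-negative")
    # evaluate on the ratio t = lam2/lam1 <= 1: R = 4t/(1+t)^2 is immune to
    # over/underflow of lam^2 for extreme eigenvalue magnitudes
    hi = np.maximum(lam1, lam2)
    lo = np.minimum(lam1, lam2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(hi > 0, lo / np.where(hi > 0, hi, 1.0), 0.0)
    R = 4.0 * t / (1.0 + t) ** 2
    return DiscontinuityField(np.clip(R, 0.0, 1.0))


def compute_discontinuity(velocity_frame: np.ndarray, sigma: float = 1.0) -> DiscontinuityField:
    """Convenience chain: structure tensor -> eigenvalues -> R."""
    return discontinuity_field(tensor_eigenvalues(structure_tensor(velocity_frame, sigma)))
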