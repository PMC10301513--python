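"""Geometric level set evolution driven by velocity and flow discontinuity.

The vessel boundary is the zero level set of a signed distance function phi
(negative inside).  The front moves with outward normal speed

    F = chi - R,

where ``chi`` is a smoothed Heaviside of the speed excess ``|v| - delta``
(Eq. gate: the front grows through high-velocity lumen) and ``R`` is the
structure-tensor discontinuity function (the front is arrested where two flow
directions coexist, i.e. at vessel walls).  The PC-MRA restricts the domain:
the speed is frozen to zero outside a thresholded-MRA mask so the front
cannot advance into noise-dominated regions.

Numerics: Godunov upwind discretisation of |grad phi|, CFL time step
``0.45 * min(spacing) / max|F|``, redistancing every 25 iterations, and
convergence when the voxelised interior is unchanged for ``tol`` consecutive
redistancing cycles (default 3), capped at 1000 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .discontinuity import DiscontinuityField
from .io import SegmentationMask

__all__ = [
    "ChiParams",
    "LevelSetState",
    "chi_field",
    "initialize_phi",
    "evolve",
    "phi_to_mask",
]

CFL = 0.45
REINIT_EVERY = 25


@dataclass
class ChiParams:
    """Speed-gate parameters: threshold ``delta`` and ramp half-width
    ``epsilon``, both in cm/s.  Defaults are tuned to clinical aortic 4D flow
    (VENC 200-550 cm/s); phantom runs scale ``delta`` to the phantom's peak
    speed."""

    delta: float = 275.0
    epsilon: float = 0.5

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")


@dataclass
class LevelSetState:
    """Signed distance function (mm, negative inside) plus bookkeeping."""

    phi: np.ndarray
    spacing: np.ndarray
    iteration: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)


def chi_field(speed_volume: np.ndarray, params: ChiParams) -> np.ndarray:
    """Smoothed Heaviside of ``|v| - delta``, valued in [0, 1].

    1 where the speed exceeds delta by more than epsilon, 0 where it falls
    short by more than epsilon, and the C1 ramp
    ``(1 + x/eps + sin(pi x / eps) / pi) / 2`` in between.
    """
    x = np.asarray(speed_volume, dtype=float) - params.delta
    eps = params.epsilon
    ramp = 0.5 * (1.0 + x / eps + np.sin(np.pi * x / eps) / np.pi)
    # the sin term leaves O(1e-17) excursions at the ramp edges
    return np.clip(np.where(x > eps, 1.0, np.where(x < -eps, 0.0, ramp)), 0.0, 1.0)


def _signed_distance(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance in mm, negative inside the mask."""
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    return outside - inside


def initialize_phi(init: SegmentationMask) -> LevelSetState:
    """Signed-distance initialisation of phi from a binary initial front."""
    m = init.voxels
    if not m.any():
        raise ValueError("initial mask is empty")
    if m.all():
        raise ValueError("initial mask covers the whole grid")
    return LevelSetState(_signed_distance(m, init.spacing), init.spacing)


def _upwind_gradients(phi: np.ndarray, spacing: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Godunov upwind |grad phi| for expansion (F>0) and contraction (F<0)."""
    grad_p_sq = np.zeros_like(phi)
    grad_m_sq = np.zeros_like(phi)
    for ax in range(3):
        h = spacing[ax]
        fwd = (np.roll(phi, -1, axis=ax) - phi) / h
        bwd = (phi - np.roll(phi, 1, axis=ax)) / h
        # one-sided differences at the boundary faces
        sl_first = [slice(None)] * 3
        sl_last = [slice(None)] * 3
        sl_first[ax] = 0
        sl_last[ax] = -1
        bwd[tuple(sl_first)] = 0.0
        fwd[tuple(sl_last)] = 0.0
        grad_p_sq += np.maximum(bwd, 0.0) ** 2 + np.minimum(fwd, 0.0) ** 2
        grad_m_sq += np.minimum(bwd, 0.0) ** 2 + np.maximum(fwd, 0.0) ** 2
    return np.sqrt(grad_p_sq), np.sqrt(grad_m_sq)


def evolve(
    state: LevelSetState,
    chi: np.ndarray,
    R: DiscontinuityField | np.ndarray,
    domain: SegmentationMask | None = None,
    max_iter: int = 1000,
    tol: int = 3,
) -> LevelSetState:
    """Evolve phi under normal speed F = chi - R, frozen outside the domain.

    Parameters
    ----------
    state : LevelSetState
        Initialised signed distance function.
    chi, R : ndarray
        Speed gate and discontinuity volumes on the same grid as phi.
    domain : SegmentationMask, optional
        Voxels where the front may move; F is set to 0 elsewhere, so the
        interior set outside the domain is exactly the initial one.
    max_iter : int
        Iteration cap (default 1000).
    tol : int
        Number of consecutive redistancing cycles with an unchanged interior
        voxel set required to declare convergence.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    r_vals = R.R if isinstance(R, DiscontinuityField) else np.asarray(R, dtype=float)
    phi = state.phi.copy()
    if chi.shape != phi.shape or r_vals.shape != phi.shape:
        raise ValueError("chi, R and phi must share a shape")
    F = np.asarray(chi, dtype=float) - r_vals
    if domain is not None:
        if domain.voxels.shape != phi.shape:
            raise ValueError("domain mask shape mismatch")
        F = np.where(domain.voxels, F, 0.0)

    max_f = float(np.max(np.abs(F)))
    spacing = state.spacing
    if max_f == 0.0:
        return LevelSetState(phi, spacing, iteration=0, converged=True)
    dt = CFL * float(spacing.min()) / max_f

    pos = F > 0
    neg = F < 0
    prev_mask = phi < 0
    unchanged = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad_p, grad_m = _upwind_gradients(phi, spacing)
        speed = np.zeros_like(phi)
        speed[pos] = F[pos] * grad_p[pos]
        speed[neg] = F[neg] * grad_m[neg]
        phi -= dt * speed
        if not np.all(np.isfinite(phi)):
            raise RuntimeError(
                f"non-finite phi at iteration {it} "
                f"(dt={dt:.3g}, max|F|={max_f:.3g})"
            )
        if it % REINIT_EVERY == 0 or it == max_iter:
            mask = phi < 0
            if mask.any() and not mask.all():
                phi = _signed_distance(mask, spacing)
            if np.array_equal(mask, prev_mask):
                unchanged += 1
                if unchanged >= tol:
                    converged = True
                    break
            else:
                unchanged = 0
            prev_mask = mask
    return LevelSetState(phi, spacing, iteration=it, converged=converged)


def phi_to_mask(state: LevelSetState) -> SegmentationMask:
    """Interior voxel set {phi < 0} as a binary mask."""
    return SegmentationMask(state.phi < 0, state.spacing)
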