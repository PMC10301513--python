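"""Phase-offset correction and magnitude normalisation.

Eddy currents leave a slowly varying, time-constant additive offset on each
phase-contrast velocity component.  The correction follows the volumetric
approach: discard low-magnitude voxels (15th percentile of the temporal-mean
magnitude), keep the candidates whose temporal velocity standard deviation is
strictly below the candidate median (stationary tissue), fit a third-degree
trivariate polynomial surface to their temporal-mean velocity by ordinary
least squares, and subtract the fitted offset volume from every frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import polybasis
from .io import FlowDataset, SegmentationMask

logger = logging.getLogger(__name__)

__all__ = [
    "OffsetModel",
    "magnitude_candidate_mask",
    "stationary_tissue_mask",
    "fit_offset_surface",
    "correct_phase_offset",
    "normalize_magnitude",
]

_DIRS = {"x": 0, "y": 1, "z": 2}


@dataclass
class OffsetModel:
    """Fitted per-direction cubic offset surfaces (cm/s).

    ``coeffs`` is (3, 20) in the fixed monomial ordering of
    :mod:`aortaflow.polybasis` on coordinates normalised to [-1, 1].
    """

    coeffs: np.ndarray = field(
        default_factory=lambda: np.zeros((3, polybasis.N_COEFFS))
    )

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (3, polybasis.N_COEFFS):
            raise ValueError(
                f"coeffs must have shape (3, {polybasis.N_COEFFS}), got {self.coeffs.shape}"
            )

    def offset_volume(self, direction: int | str, shape: tuple[int, int, int]) -> np.ndarray:
        d = _DIRS.get(direction, direction)
        return polybasis.evaluate(self.coeffs[d], shape)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "basis": "trivariate monomials, total degree <= 3, "
                    "ordering (degree, i, j, k) on [-1,1] coords",
                    "units": "cm/s",
                    "coeffs": self.coeffs.tolist(),
                }
            )
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OffsetModel":
        data = yaml.safe_load(Path(path).read_text())
        return cls(np.asarray(data["coeffs"], dtype=float))


def magnitude_candidate_mask(ds: FlowDataset, percentile: float = 15.0) -> SegmentationMask:
    """Voxels whose temporal-mean magnitude reaches the given percentile.

    The threshold is the linear-interpolation percentile of the temporal-mean
    magnitude volume; voxels >= threshold are retained.
    """
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    if ds.magnitude.size == 0:
        raise ValueError("empty dataset")
    mean_mag = ds.magnitude.mean(axis=3)
    threshold = np.percentile(mean_mag, percentile)
    return SegmentationMask(mean_mag >= threshold, ds.spacing)


def stationary_tissue_mask(
    ds: FlowDataset, candidates: SegmentationMask, direction: str | int
) -> SegmentationMask:
    """Candidate voxels with below-median temporal velocity s.d. (one direction).

    A voxel is stationary when the temporal standard deviation of the given
    velocity component is strictly below the median temporal s.d. over the
    candidate set.  In degenerate distributions (e.g. noise-free data where
    most candidates have s.d. exactly 0 = median) the strict comparison
    selects nothing; the documented fallback relaxes it to <= median, which
    keeps exactly the minimal-s.d. voxels and reduces to "all candidates"
    when every s.d. is identical.
    """
    d = _DIRS.get(direction, direction)
    if candidates.n_voxels == 0:
        raise ValueError("candidate mask is empty")
    sd = ds.velocity[..., d].std(axis=3)
    cand = candidates.voxels
    median_sd = np.median(sd[cand])
    selected = cand & (sd < median_sd)
    if not selected.any():
        logger.info(
            "degenerate temporal s.d. distribution (direction %s): "
            "falling back to s.d. <= median",
            direction,
        )
        selected = cand & (sd <= median_sd)
    return SegmentationMask(selected, ds.spacing)


def fit_offset_surface(
    ds: FlowDataset, stationary: SegmentationMask, direction: str | int
) -> tuple[OffsetModel, np.ndarray]:
    """OLS fit of a cubic surface to temporal-mean velocity at stationary voxels.

    Returns an :class:`OffsetModel` with the requested direction filled and
    the evaluated offset volume (cm/s) on the full grid.
    """
    d = _DIRS.get(direction, direction)
    n = stationary.n_voxels
    if n < polybasis.N_COEFFS:
        raise ValueError(
            f"need at least {polybasis.N_COEFFS} stationary voxels to fit, got {n}"
        )
    shape = ds.spatial_shape
    xg, yg, zg = polybasis.normalized_coords(shape)
    sel = stationary.voxels
    A = polybasis.design_matrix(xg[sel], yg[sel], zg[sel])
    b = ds.velocity[..., d].mean(axis=3)[sel]
    coeffs, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < polybasis.N_COEFFS:
        raise ValueError(
            f"rank-deficient design matrix (rank {rank} < {polybasis.N_COEFFS}); "
            "stationary voxels do not constrain a cubic surface"
        )
    model = OffsetModel()
    model.coeffs[d] = coeffs
    return model, polybasis.evaluate(coeffs, shape)


def correct_phase_offset(
    ds: FlowDataset, percentile: float = 15.0
) -> tuple[FlowDataset, OffsetModel]:
    """Fit and subtract the per-direction phase offset from every frame."""
    candidates = magnitude_candidate_mask(ds, percentile)
    out = ds.copy()
    model = OffsetModel()
    for direction in range(3):
        stationary = stationary_tissue_mask(ds, candidates, direction)
        fitted, offset = fit_offset_surface(ds, stationary, direction)
        model.coeffs[direction] = fitted.coeffs[direction]
        out.velocity[..., direction] -= offset[..., None]
    return out, model


def normalize_magnitude(ds: FlowDataset) -> FlowDataset:
    """Affinely map the 4D magnitude onto [0, 1]; velocities untouched."""
    lo = float(ds.magnitude.min())
    hi = float(ds.magnitude.max())
    if hi == lo:
        raise ValueError("magnitude volume is constant; cannot normalise")
    out = ds.copy()
    out.magnitude = (ds.magnitude - lo) / (hi - lo)
    return out
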