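"""Data model and NIfTI readers/writers for 4D flow datasets, masks and labels.

Conventions
-----------
* Volumes are indexed ``(x, y, z)``; 4D arrays append time as the last axis
  ``(x, y, z, t)`` and velocity adds a trailing component axis
  ``(x, y, z, t, 3)``.
* World coordinates are ``index * spacing`` in millimetres with the origin at
  voxel ``(0, 0, 0)``.  Orientation information beyond voxel spacing is
  ignored (a warning is logged when a non-diagonal affine is encountered):
  phantom and patient pipelines are self-consistent in this frame.
* Velocity is stored in cm/s throughout the package; only the wall shear
  stress module converts to SI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "FlowDataset",
    "SegmentationMask",
    "RegionLabels",
    "read_dataset",
    "write_dataset",
    "read_mask",
    "write_mask",
    "read_labels",
    "write_labels",
]


@dataclass
class FlowDataset:
    """Time-resolved phase-contrast MRI data.

    Parameters
    ----------
    magnitude : ndarray, shape (X, Y, Z, T)
        Anatomical magnitude signal (arbitrary units, non-negative).
    velocity : ndarray, shape (X, Y, Z, T, 3)
        Velocity components in cm/s, ordered (vx, vy, vz).
    spacing : ndarray, shape (3,)
        Voxel spacing in mm.
    frame_times : ndarray, shape (T,)
        Trigger times of the cardiac frames in ms.
    venc : float
        Velocity encoding limit in cm/s.
    """

    magnitude: np.ndarray
    velocity: np.ndarray
    spacing: np.ndarray
    frame_times: np.ndarray
    venc: float

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.magnitude.ndim != 4:
            raise ValueError("magnitude must be 4D (X, Y, Z, T)")
        if self.velocity.shape != self.magnitude.shape + (3,):
            raise ValueError(
                f"velocity shape {self.velocity.shape} inconsistent with "
                f"magnitude shape {self.magnitude.shape}"
            )
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive values (mm)")
        if self.frame_times.shape != (self.magnitude.shape[3],):
            raise ValueError("frame_times length must equal number of frames")
        vmax = float(np.max(np.abs(self.velocity))) if self.velocity.size else 0.0
        if self.venc > 0 and vmax > self.venc:
            logger.warning(
                "velocity magnitude %.1f cm/s exceeds VENC %.1f cm/s; "
                "assuming data were pre-unwrapped",
                vmax,
                self.venc,
            )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[3]

    def speed(self, frame: int | None = None) -> np.ndarray:
        """Velocity magnitude |v| in cm/s, per frame or for one frame."""
        v = self.velocity if frame is None else self.velocity[..., frame, :]
        return np.sqrt(np.sum(v**2, axis=-1))

    def copy(self) -> "FlowDataset":
        return FlowDataset(
            self.magnitude.copy(),
            self.velocity.copy(),
            self.spacing.copy(),
            self.frame_times.copy(),
            self.venc,
        )


@dataclass
class SegmentationMask:
    """Binary 3D segmentation with voxel spacing in mm."""

    voxels: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive values (mm)")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def copy(self) -> "SegmentationMask":
        return SegmentationMask(self.voxels.copy(), self.spacing.copy())


#: Default legend for the three aortic regions.
DEFAULT_LEGEND = {1: "ascending incl. arch", 2: "descending thoracic", 3: "abdominal"}


@dataclass
class RegionLabels:
    """Integer region-label volume (0 = background) with a legend."""

    labels: np.ndarray
    legend: dict = field(default_factory=lambda: dict(DEFAULT_LEGEND))
    spacing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(np.int32)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.spacing is not None:
            self.spacing = np.asarray(self.spacing, dtype=float)

    def region_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]


# ---------------------------------------------------------------------------
# NIfTI helpers
# ---------------------------------------------------------------------------


def _affine(spacing: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; return (data, spacing_mm)."""
    img = nib.load(str(path))
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        logger.warning("non-diagonal affine in %s; orientation ignored, spacing kept", path)
    return np.asarray(img.dataobj, dtype=np.float64), zooms


def _save_volume(data: np.ndarray, spacing: np.ndarray, path: str | Path, dtype=None) -> None:
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    img = nib.Nifti1Image(arr, _affine(np.asarray(spacing, dtype=float)))
    img.header.set_zooms(tuple(spacing) + (1.0,) * (arr.ndim - 3))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Dataset manifest I/O
# ---------------------------------------------------------------------------


def write_dataset(ds: FlowDataset, directory: str | Path, stem: str = "flow") -> Path:
    """Write a dataset as 4 NIfTI files plus a YAML manifest; return manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = {}
    _save_volume(ds.magnitude, ds.spacing, directory / f"{stem}_mag.nii.gz")
    names["magnitude"] = f"{stem}_mag.nii.gz"
    for i, comp in enumerate("xyz"):
        _save_volume(ds.velocity[..., i], ds.spacing, directory / f"{stem}_v{comp}.nii.gz")
        names[f"velocity_{comp}"] = f"{stem}_v{comp}.nii.gz"
    manifest = {
        "files": names,
        "spacing_mm": [float(s) for s in ds.spacing],
        "frame_times_ms": [float(t) for t in ds.frame_times],
        "venc_cm_s": float(ds.venc),
        "velocity_dialect": "physical",
    }
    path = directory / f"{stem}_manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def read_dataset(manifest: str | Path) -> FlowDataset:
    """Read a 4D flow dataset described by a YAML manifest.

    The manifest lists the four component files, spacing, VENC and frame
    times, and declares the storage dialect of the velocity volumes:

    * ``physical`` — volumes already hold cm/s, passed through unchanged;
    * ``raw`` — volumes hold scaled integers, converted as
      ``v = raw / raw_max * VENC`` (``raw_max`` defaults to 32767).
    """
    manifest = Path(manifest)
    meta = yaml.safe_load(manifest.read_text())
    files = meta["files"]
    base = manifest.parent
    mag, spacing = _load_volume(base / files["magnitude"])
    comps = []
    for comp in "xyz":
        vol, sp = _load_volume(base / files[f"velocity_{comp}"])
        if vol.shape != mag.shape:
            raise ValueError(
                f"velocity_{comp} shape {vol.shape} does not match magnitude {mag.shape}"
            )
        if not np.allclose(sp, spacing, atol=1e-6):
            raise ValueError(f"velocity_{comp} spacing {sp} differs from magnitude {spacing}")
        comps.append(vol)
    velocity = np.stack(comps, axis=-1)

    dialect = meta.get("velocity_dialect", "physical")
    venc = meta.get("venc_cm_s")
    if dialect == "raw":
        if venc is None:
            raise ValueError("raw velocity dialect requires venc_cm_s in the manifest")
        raw_max = float(meta.get("raw_max", 32767))
        velocity = velocity / raw_max * float(venc)
    elif dialect != "physical":
        raise ValueError(f"unknown velocity dialect {dialect!r}")

    spacing = np.asarray(meta.get("spacing_mm", spacing), dtype=float)
    n_frames = mag.shape[3] if mag.ndim == 4 else 1
    if mag.ndim == 3:
        mag = mag[..., None]
        velocity = velocity[..., None, :] if velocity.ndim == 4 else velocity
    frame_times = np.asarray(
        meta.get("frame_times_ms", np.arange(n_frames, dtype=float)), dtype=float
    )
    return FlowDataset(mag, velocity, spacing, frame_times, float(venc or 0.0))


# ---------------------------------------------------------------------------
# Mask / label I/O
# ---------------------------------------------------------------------------


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    """Write a binary mask as unsigned 8-bit NIfTI (0/1)."""
    _save_volume(mask.voxels.astype(np.uint8), mask.spacing, path, dtype=np.uint8)


def read_mask(path: str | Path) -> SegmentationMask:
    data, spacing = _load_volume(path)
    vals = np.unique(data)
    if not np.all(np.isin(vals, [0, 1])):
        raise ValueError(
            f"{path}: mask contains non-binary values {vals[:5]}; expected 0/1 volume"
        )
    return SegmentationMask(data > 0.5, spacing)


def write_labels(labels: RegionLabels, spacing: np.ndarray, path: str | Path) -> None:
    _save_volume(labels.labels.astype(np.uint8), spacing, path, dtype=np.uint8)


def read_labels(path: str | Path, legend: dict | None = None) -> RegionLabels:
    data, spacing = _load_volume(path)
    return RegionLabels(
        np.rint(data).astype(np.int32),
        legend=legend or dict(DEFAULT_LEGEND),
        spacing=spacing,
    )
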