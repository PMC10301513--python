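"""Synthetic 4D flow phantoms with known lumen geometry and analytic flow.

The generator emulates a thoracic 4D flow acquisition at desk scale: a rigid
tube (straight, or U-shaped as an aorta analogue) carrying laminar Poiseuille
flow with a systolic peak, embedded in stationary tissue with an air margin,
optionally corrupted by Rician magnitude noise, Gaussian velocity noise and a
time-constant third-degree polynomial phase offset per velocity direction.

Because the in-lumen profile is exactly parabolic with no-slip walls, the
analytic wall shear stress ``tau_w = 2 mu v_max / R`` is known per frame and
is stored in :class:`PhantomTruth` as the oracle for the WSS pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

from . import polybasis
from .io import (
    DEFAULT_LEGEND,
    FlowDataset,
    RegionLabels,
    SegmentationMask,
    write_dataset,
    write_labels,
    write_mask,
)

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "default_waveform",
    "make_tube_phantom",
    "add_noise",
    "apply_phase_offset",
    "save_phantom",
]

#: Default blood viscosity, 3.2 cP in Pa*s.
DEFAULT_MU_PA_S = 3.2e-3


def default_waveform(
    n_frames: int = 25, peak: float = 100.0, systolic_frame: int = 8
) -> np.ndarray:
    """Smooth single-peak systolic waveform in cm/s.

    A raised-cosine pulse of half-width ``n_frames / 4`` centred on the
    systolic frame, zero in diastole — the shape of a healthy aortic flow
    curve at the temporal resolution of a 25-frame acquisition.
    """
    t = np.arange(n_frames, dtype=float)
    half_width = n_frames / 4.0
    x = (t - systolic_frame) / half_width
    w = np.where(np.abs(x) < 1.0, 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)
    return peak * w


@dataclass
class PhantomConfig:
    """Configuration of a synthetic tube phantom.

    Defaults reproduce the acquisition geometry the pipeline targets:
    64³ voxels at 2×2×2 mm³, 25 cardiac frames, a 10 mm tube radius and a
    100 cm/s systolic peak.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_frames: int = 25
    tube_radius: float = 10.0
    geometry: str = "straight"
    v_max_waveform: np.ndarray | None = None
    systolic_frame: int = 8
    lumen_magnitude: float = 1.0
    tissue_magnitude: float = 0.6
    air_magnitude: float = 0.05
    noise_sd: float = 0.0
    offset_coeffs: np.ndarray | None = None
    seed: int = 0
    frame_interval_ms: float = 36.0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be 3 positive reals (mm)")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be positive (mm)")
        if self.geometry not in ("straight", "u_bend"):
            raise ValueError("geometry must be 'straight' or 'u_bend'")
        if self.v_max_waveform is None:
            self.v_max_waveform = default_waveform(self.n_frames, 100.0, self.systolic_frame)
        self.v_max_waveform = np.asarray(self.v_max_waveform, dtype=float)
        if self.v_max_waveform.shape != (self.n_frames,):
            raise ValueError("v_max_waveform must have n_frames entries")
        if np.any(self.v_max_waveform < 0):
            raise ValueError("v_max_waveform must be non-negative")
        if self.v_max_waveform.max() > 0 and (
            int(np.argmax(self.v_max_waveform)) != self.systolic_frame
        ):
            raise ValueError("waveform peak must sit at systolic_frame")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.offset_coeffs is not None:
            self.offset_coeffs = np.asarray(self.offset_coeffs, dtype=float)
            if self.offset_coeffs.shape != (3, polybasis.N_COEFFS):
                raise ValueError(
                    f"offset_coeffs must have shape (3, {polybasis.N_COEFFS})"
                )

    @property
    def v_peak(self) -> float:
        return float(self.v_max_waveform[self.systolic_frame])


@dataclass
class PhantomTruth:
    """Ground-truth surrogate attached to a generated phantom."""

    lumen_mask: SegmentationMask
    region_labels: RegionLabels
    #: analytic maximum wall shear stress, shape (n_regions, n_frames), Pa
    analytic_max_wss: np.ndarray
    mu_pa_s: float = DEFAULT_MU_PA_S
    systolic_frame: int = 0

    def max_wss_at_systole(self, region: int | None = None) -> float:
        idx = 0 if region is None else region - 1
        return float(self.analytic_max_wss[idx, self.systolic_frame])


# ---------------------------------------------------------------------------
# centerline construction
# ---------------------------------------------------------------------------


def _centerline(config: PhantomConfig) -> np.ndarray:
    """Densely sampled centerline points in mm, shape (n, 3)."""
    nx, ny, nz = config.grid_shape
    sx, sy, sz = config.spacing
    extent = np.array([(nx - 1) * sx, (ny - 1) * sy, (nz - 1) * sz])
    step = 0.25 * min(config.spacing)
    cy = extent[1] / 2.0

    if config.geometry == "straight":
        cx = extent[0] / 2.0
        z = np.arange(0.0, extent[2] + step / 2, step)
        pts = np.column_stack([np.full_like(z, cx), np.full_like(z, cy), z])
        return pts

    # u_bend: two vertical limbs joined by a semicircular arch at high z,
    # the second limb extended distally (abdominal analogue).
    margin = config.tube_radius + 2.0 * max(config.spacing)
    x1, x2 = margin, extent[0] - margin
    arch_r = (x2 - x1) / 2.0
    z_top = extent[2] - margin - arch_r
    z_bot = margin
    if arch_r <= 0 or z_top <= z_bot:
        raise ValueError("u_bend tube does not fit in the grid with a 2-voxel margin")

    pts = []
    z_up = np.arange(z_bot, z_top, step)
    pts.append(np.column_stack([np.full_like(z_up, x1), np.full_like(z_up, cy), z_up]))
    n_arc = max(int(np.pi * arch_r / step), 8)
    theta = np.linspace(np.pi, 0.0, n_arc)
    cx_a = (x1 + x2) / 2.0
    pts.append(
        np.column_stack(
            [cx_a + arch_r * np.cos(theta), np.full(n_arc, cy), z_top + arch_r * np.sin(theta)]
        )
    )
    z_dn = np.arange(z_top, z_bot, -step)
    pts.append(np.column_stack([np.full_like(z_dn, x2), np.full_like(z_dn, cy), z_dn]))
    return np.concatenate(pts, axis=0)


def _check_fit(config: PhantomConfig, centerline: np.ndarray) -> None:
    # the tube must keep a >= 2-voxel margin on every axis it extends
    # radially into; a straight tube crosses the volume along z by design
    axes = (0, 1) if config.geometry == "straight" else (0, 1, 2)
    extent = (np.array(config.grid_shape) - 1) * np.array(config.spacing)
    margin = 2.0 * np.array(config.spacing)
    lo = centerline.min(axis=0) - config.tube_radius
    hi = centerline.max(axis=0) + config.tube_radius
    for ax in axes:
        if lo[ax] < margin[ax] - 1e-9 or hi[ax] > extent[ax] - margin[ax] + 1e-9:
            raise ValueError(
                "tube of radius %.1f mm does not fit in the grid with a "
                "2-voxel margin (axis %d)" % (config.tube_radius, ax)
            )


def _tube_geometry(
    config: PhantomConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel distance to the centerline, local unit tangent and
    normalised arc-length of the closest centerline point.

    Returns (r, tangent, arc_frac) with shapes (X,Y,Z), (X,Y,Z,3), (X,Y,Z).
    """
    pts = _centerline(config)
    _check_fit(config, pts)
    seg = np.gradient(pts, axis=0)
    tangents = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    arc_frac_line = arc / arc[-1]

    shape = config.grid_shape
    coords = np.stack(
        np.meshgrid(
            *[np.arange(n) * s for n, s in zip(shape, config.spacing)], indexing="ij"
        ),
        axis=-1,
    ).reshape(-1, 3)
    tree = cKDTree(pts)
    _, idx = tree.query(coords, workers=-1)
    d = coords - pts[idx]
    t = tangents[idx]
    # remove the along-tangent component so r is the true perpendicular
    # distance (exact for straight segments, second order for arcs)
    d_perp = d - (np.sum(d * t, axis=1, keepdims=True)) * t
    r = np.linalg.norm(d_perp, axis=1).reshape(shape)
    tangent = t.reshape(shape + (3,))
    arc_frac = arc_frac_line[idx].reshape(shape)
    return r, tangent, arc_frac


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------


def make_tube_phantom(config: PhantomConfig) -> tuple[FlowDataset, PhantomTruth]:
    """Generate a rigid tube phantom with Poiseuille flow.

    The axial velocity inside the lumen is ``v(r, t) = v_max(t) (1 - (r/R)^2)``
    along the local centerline tangent and exactly zero outside; the magnitude
    volume is piecewise constant (lumen / tissue / air).  Noise and phase
    offsets configured in ``config`` are applied on top of the clean fields.
    """
    shape = config.grid_shape
    R = config.tube_radius
    r, tangent, arc_frac = _tube_geometry(config)
    lumen = r < R

    # region labels by centerline arc-length thirds: proximal limb (plus arch
    # onset) ~ ascending, mid ~ descending, distal ~ abdominal analogue
    labels = np.zeros(shape, dtype=np.int32)
    thirds = np.clip((arc_frac * 3).astype(int) + 1, 1, 3)
    labels[lumen] = thirds[lumen]

    # magnitude: air frame of 3 voxels around a tissue body, bright lumen
    body = np.zeros(shape, dtype=bool)
    body[3:-3, 3:-3, 3:-3] = True
    mag3d = np.where(body, config.tissue_magnitude, config.air_magnitude)
    mag3d = np.where(lumen, config.lumen_magnitude, mag3d)

    profile = np.where(lumen, 1.0 - (r / R) ** 2, 0.0)
    T = config.n_frames
    magnitude = np.repeat(mag3d[..., None], T, axis=3)
    velocity = (
        profile[..., None, None]
        * config.v_max_waveform[None, None, None, :, None]
        * tangent[..., None, :]
    )

    frame_times = np.arange(T, dtype=float) * config.frame_interval_ms
    venc = max(200.0, 1.25 * float(config.v_max_waveform.max()))
    ds = FlowDataset(magnitude, velocity, np.array(config.spacing), frame_times, venc)

    if config.offset_coeffs is not None and np.any(config.offset_coeffs != 0):
        ds = apply_phase_offset(ds, config.offset_coeffs)
    if config.noise_sd > 0:
        ds = add_noise(ds, config.noise_sd, config.seed)

    # analytic Poiseuille wall shear stress per region and frame (SI):
    # tau_w = mu * 2 v_max / R, identical in every region of a rigid tube
    v_si = config.v_max_waveform / 100.0  # cm/s -> m/s
    r_si = R / 1000.0  # mm -> m
    tau = DEFAULT_MU_PA_S * 2.0 * v_si / r_si
    n_regions = int(labels.max()) if labels.max() > 0 else 1
    truth = PhantomTruth(
        lumen_mask=SegmentationMask(lumen, np.array(config.spacing)),
        region_labels=RegionLabels(labels, dict(DEFAULT_LEGEND), np.array(config.spacing)),
        analytic_max_wss=np.tile(tau, (n_regions, 1)),
        mu_pa_s=DEFAULT_MU_PA_S,
        systolic_frame=config.systolic_frame,
    )
    return ds, truth


def add_noise(ds: FlowDataset, noise_sd: float, seed: int, magnitude_sd: float | None = None) -> FlowDataset:
    """Corrupt a dataset with MR-like noise, reproducibly.

    Velocity components receive additive Gaussian noise of s.d. ``noise_sd``
    (cm/s).  The magnitude receives Rician noise — the modulus of the complex
    signal plus two-channel Gaussian noise — with channel s.d.
    ``magnitude_sd`` (default ``noise_sd / 100``, since the phantom magnitude
    is O(1) a.u. while velocities are O(100) cm/s).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return ds.copy()
    if magnitude_sd is None:
        magnitude_sd = noise_sd / 100.0
    rng = np.random.default_rng(seed)
    out = ds.copy()
    g1 = rng.normal(0.0, magnitude_sd, ds.magnitude.shape)
    g2 = rng.normal(0.0, magnitude_sd, ds.magnitude.shape)
    out.magnitude = np.sqrt((ds.magnitude + g1) ** 2 + g2**2)
    out.velocity = ds.velocity + rng.normal(0.0, noise_sd, ds.velocity.shape)
    return out


def apply_phase_offset(ds: FlowDataset, coeffs: np.ndarray) -> FlowDataset:
    """Add a time-constant cubic polynomial offset to each velocity direction.

    ``coeffs`` is (3, 20): one 20-term cubic per direction, evaluated on
    normalised voxel coordinates (see :mod:`aortaflow.polybasis`) in cm/s.
    This is the corruption that :func:`aortaflow.preprocess.correct_phase_offset`
    removes.
    """
    coeffs = np.asarray(getattr(coeffs, "coeffs", coeffs), dtype=float)
    if coeffs.shape != (3, polybasis.N_COEFFS):
        raise ValueError(f"expected (3, {polybasis.N_COEFFS}) coefficients, got {coeffs.shape}")
    out = ds.copy()
    for d in range(3):
        offset = polybasis.evaluate(coeffs[d], ds.spatial_shape)
        out.velocity[..., d] += offset[..., None]
    return out


def save_phantom(
    ds: FlowDataset, truth: PhantomTruth, directory: str | Path, config: PhantomConfig | None = None
) -> Path:
    """Write the phantom dataset, truth volumes and a YAML sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = write_dataset(ds, directory, stem="phantom")
    write_mask(truth.lumen_mask, directory / "phantom_lumen.nii.gz")
    write_labels(truth.region_labels, truth.lumen_mask.spacing, directory / "phantom_regions.nii.gz")
    sidecar = {
        "spacing_mm": [float(s) for s in ds.spacing],
        "venc_cm_s": float(ds.venc),
        "frame_times_ms": [float(t) for t in ds.frame_times],
        "systolic_frame": int(truth.systolic_frame),
        "mu_pa_s": float(truth.mu_pa_s),
        "seed": int(config.seed) if config is not None else None,
        "analytic_max_wss_pa": np.asarray(truth.analytic_max_wss).tolist(),
    }
    (directory / "phantom_truth.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return manifest
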