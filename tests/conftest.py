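import numpy as np
import pytest

import aortaflow as af


@pytest.fixture(scope="session")
def phantom_default():
    """Zero-noise straight-tube phantom at the default acquisition geometry
    (64 cubed, 2 mm, 25 frames, 10 mm radius, 100 cm/s systolic peak)."""
    cfg = af.PhantomConfig()
    ds, truth = af.make_tube_phantom(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def phantom_small():
    """Small, fast phantom for I/O and unit tests."""
    cfg = af.PhantomConfig(
        grid_shape=(24, 24, 24),
        n_frames=5,
        tube_radius=6.0,
        systolic_frame=2,
        v_max_waveform=af.default_waveform(5, 80.0, 2),
    )
    ds, truth = af.make_tube_phantom(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def phantom_ubend():
    cfg = af.PhantomConfig(geometry="u_bend")
    ds, truth = af.make_tube_phantom(cfg)
    return cfg, ds, truth


@pytest.fixture
def sphere_mask():
    """Factory for a digital sphere mask (radius in mm, isotropic spacing)."""

    def make(radius_mm=10.0, n=40, spacing=1.0):
        x = np.arange(n) * spacing
        c = x.mean()
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        vox = (X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 < radius_mm**2
        return af.SegmentationMask(vox, np.full(3, spacing))

    return make
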