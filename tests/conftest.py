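"""Shared fixtures: small grids, a compact NEMA-style phantom, and fast
acquisition settings sized for unit testing."""

from __future__ import annotations

import numpy as np
import pytest

from spectdose.phantoms import PhantomSpec, SphereSpec, make_grid
from spectdose.simulate import AcquisitionConfig


@pytest.fixture
def nm_grid16():
    return make_grid((16, 16, 16), (4.42, 4.42, 4.42), "NM")


@pytest.fixture
def nm_grid32():
    return make_grid((32, 32, 32), (4.42, 4.42, 4.42), "NM")


@pytest.fixture
def small_cfg():
    """Noise-free, scatter-free, blur-free acquisition on a 16-pixel camera."""
    return AcquisitionConfig(
        n_angles=12,
        det_pixels=(16, 16),
        noise=False,
        scatter_fraction=0.0,
        psf_sigma_mm=0.0,
    )


@pytest.fixture
def compact_nema_spec():
    """Three hot spheres on a 40-mm ring in a 65-mm-radius body: the standard
    sphere sizes and fills, scaled to fit a 32-pixel field of view."""
    angles = np.deg2rad([90.0, 210.0, 330.0])
    fills = [(37.0, 0.63), (28.0, 0.27), (22.0, 0.13)]
    spheres = tuple(
        SphereSpec(d, (40.0 * np.cos(a), 40.0 * np.sin(a), 0.0), act)
        for (d, act), a in zip(fills, angles)
    )
    return PhantomSpec(body_semi_axes_mm=(65.0, 65.0), body_length_mm=120.0, spheres=spheres)
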