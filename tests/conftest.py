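"""Shared fixtures: small deterministic phantoms and study datasets."""

import numpy as np
import pytest

from qpactvi.grids import GridSpec
from qpactvi.phantom import PhantomConfig, make_breast_phantom


@pytest.fixture(scope="session")
def tumor_phantom():
    """48^3, 0.5 mm phantom with a middle tumor."""
    cfg = PhantomConfig(
        grid=GridSpec((48, 48, 48), 0.5),
        breast_radius_mm=10.0,
        tumor_location="middle",
        tumor_radius_mm=2.4,
    )
    return make_breast_phantom(cfg, seed=7)


@pytest.fixture(scope="session")
def base_phantom():
    """Tumor-free 48^3 twin-capable phantom."""
    cfg = PhantomConfig(
        grid=GridSpec((48, 48, 48), 0.5),
        breast_radius_mm=10.0,
        tumor_radius_mm=2.4,
    )
    return make_breast_phantom(cfg, seed=7)


@pytest.fixture(scope="session")
def ring_2d_setup():
    """Homogeneous 2D medium + full ring array, shared by acoustics tests."""
    from qpactvi.acoustics import TransducerArray
    from qpactvi.phantom import AcousticMaps

    grid = GridSpec((128, 128), 0.5, origin=(-31.75, -31.75))
    c0, rho0 = 1500.0, 1000.0
    acoustic = AcousticMaps(
        c=np.full(grid.shape, c0), rho=np.full(grid.shape, rho0),
        alpha0=np.zeros(grid.shape), y=np.ones(grid.shape))
    dt = 0.3 * grid.voxel_size * 1e-3 / c0
    array = TransducerArray.ring_2d(128, 25.0, (0.0, 0.0), 1.0 / dt, 560)
    return grid, acoustic, array, c0, rho0
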