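import numpy as np
import pytest

import robustpet as rp


@pytest.fixture(scope="session")
def tiny_geom():
    return rp.ScanGeometry(grid_nx=8, grid_ny=8, n_angles=10, n_bins=11)


@pytest.fixture(scope="session")
def tiny_D(tiny_geom):
    return rp.build_system_matrix(tiny_geom)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_geom):
    return rp.shepp_logan_phantom(tiny_geom)


@pytest.fixture(scope="session")
def small_geom():
    return rp.ScanGeometry(grid_nx=32, grid_ny=32, n_angles=30, n_bins=47)


@pytest.fixture(scope="session")
def small_D(small_geom):
    return rp.build_system_matrix(small_geom)


@pytest.fixture(scope="session")
def small_phantom(small_geom):
    return rp.shepp_logan_phantom(small_geom)


@pytest.fixture(scope="session")
def toy_geom():
    """4-pixel grid with a 9-ray parallel-beam layout."""
    return rp.ScanGeometry(grid_nx=2, grid_ny=2, n_angles=3, n_bins=3)


@pytest.fixture(scope="session")
def toy_D(toy_geom):
    return rp.build_system_matrix(toy_geom)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_ray_length(geom, point, direction, step_factor=1e-4):
    """Independent sampled-ray oracle: march along the ray, accumulate the
    in-pixel step lengths for every pixel.  Returns a dense (ny*nx,) vector."""
    step = step_factor * geom.pixel_size
    half_diag = float(np.hypot(geom.width, geom.height))
    ts = np.arange(-half_diag, half_diag, step)
    pts = point[None, :] + direction[None, :] * ts[:, None]
    ix = np.floor((pts[:, 0] + geom.width / 2) / geom.pixel_size).astype(int)
    iy = np.floor((pts[:, 1] + geom.height / 2) / geom.pixel_size).astype(int)
    ok = (ix >= 0) & (ix < geom.grid_nx) & (iy >= 0) & (iy < geom.grid_ny)
    out = np.zeros(geom.n_voxels)
    np.add.at(out, iy[ok] * geom.grid_nx + ix[ok], step)
    return out
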