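import numpy as np
import pytest

import wmchi as w


@pytest.fixture(scope="session")
def ctx():
    return w.FieldContext()


@pytest.fixture(scope="session")
def small_grid():
    return w.GridSpec((32, 32, 32), (1.0, 1.0, 1.0), pad_factor=2.0)


@pytest.fixture(scope="session")
def brain_model():
    """Default brain model on the unpadded (circularly consistent) grid."""
    return w.make_brain_model(w.GridSpec((64, 64, 64), (3.0, 3.0, 3.0), 1.0), seed=0)


@pytest.fixture(scope="session")
def brain_model_padded():
    """Same brain model with physical (pad-2) forward simulation."""
    return w.make_brain_model(w.GridSpec((64, 64, 64), (3.0, 3.0, 3.0), 2.0), seed=0)


@pytest.fixture(scope="session")
def phantom_study():
    """Full nerve-phantom susceptometry study at the default study conditions."""
    from wmchi.pipelines import nerve_susceptometry

    return nerve_susceptometry()


def sphere_mask(grid, radius, center=(0.0, 0.0, 0.0)):
    x, y, z = grid.coords()
    return ((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2) <= radius**2


def smooth_tensor_blob(grid, seed=0, sigma=1.2, amplitude=0.05):
    """Gaussian-windowed uniform random tensor at the grid centre.

    The Fourier dipole model is a mid-band representation: a smooth compact
    source keeps both it and the continuum real-space oracle in their common
    regime, away from single-voxel ringing.
    """
    rng = np.random.default_rng(seed)
    mat = rng.normal(0, 1, (3, 3))
    T = amplitude * (mat + mat.T)
    x, y, z = grid.coords()
    g = np.exp(-(np.broadcast_to(x**2 + y**2 + z**2, grid.shape)) / (2 * sigma**2))
    g[g < 1e-4] = 0.0  # keep the source compact, clear of the evaluation shell
    mats = g[..., None, None] * T
    return w.SymmetricTensorVolume.from_matrix_field(mats, grid)


def real_space_tensor_oracle(X, ctx, r_min, r_max):
    """Brute-force O(N^2) sum of continuum point-tensor dipole responses.

    Returns the predicted frequency map on the evaluation shell
    ``r_min <= |r - centre| <= r_max`` (zero elsewhere) and the shell mask.
    """
    grid = X.grid
    h = ctx.h
    x, y, z = grid.coords()
    xx = np.broadcast_to(x, grid.shape)
    yy = np.broadcast_to(y, grid.shape)
    zz = np.broadcast_to(z, grid.shape)
    r0 = np.sqrt(xx**2 + yy**2 + zz**2)
    shell = (r0 >= r_min) & (r0 <= r_max)
    mats = X.as_matrix_field()
    sources = np.argwhere(np.abs(mats).max(axis=(-2, -1)) > 0)
    pred = np.zeros(grid.shape)
    pts = np.stack([xx[shell], yy[shell], zz[shell]], axis=-1)
    acc = np.zeros(len(pts))
    voxel_vol = float(np.prod(grid.voxel_size))
    for src in sources:
        T = mats[tuple(src)]
        Th = T @ h
        d = pts - np.array([xx[tuple(src)], yy[tuple(src)], zz[tuple(src)]])
        r = np.linalg.norm(d, axis=-1)
        rhat = d / r[:, None]
        acc += (
            voxel_vol
            / (4 * np.pi * r**3)
            * (3 * (rhat @ h) * (rhat @ Th) - h @ Th)
        )
    pred[shell] = ctx.larmor_scale * acc
    return pred, shell
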