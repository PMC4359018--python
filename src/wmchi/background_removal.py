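"""SHARP background-field removal.

Fields generated by susceptibility sources located outside a closed mask are
harmonic inside the mask, and harmonic functions satisfy the spherical mean
value property: convolving with any normalised sphere leaves them unchanged.
SHARP exploits this by applying the operator ``(delta - rho)`` (identity minus
a normalised spherical kernel of radius R), which annihilates the harmonic
background, and then deconvolving the same operator with truncated-SVD
regularisation to restore the internal (non-harmonic) field.  The result is
only defined on the mask eroded by R, and is returned with its mean over the
eroded mask removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft

from .morphology import erode
from .volumes import GridSpec, ScalarVolume

__all__ = ["SharpParams", "sharp_filter"]


@dataclass(frozen=True)
class SharpParams:
    """SHARP settings.

    ``kernel_radius`` is the spherical-mean-value kernel radius in mm;
    ``tsvd_threshold`` truncates the deconvolution where ``|1 - rho_hat|``
    falls below it; ``erosion_vox`` is the mask erosion in voxels (default:
    derived from the kernel radius).
    """

    kernel_radius: float = 4.0
    tsvd_threshold: float = 0.05
    erosion_vox: float | None = None

    def __post_init__(self):
        if not self.kernel_radius > 0:
            raise ValueError("kernel radius must be positive")
        if not 0 < self.tsvd_threshold < 1:
            raise ValueError("TSVD threshold must be in (0, 1)")
        if self.erosion_vox is not None and self.erosion_vox < 1:
            raise ValueError("erosion must be at least 1 voxel")


def _smv_kernel_hat(grid: GridSpec, radius_mm: float) -> np.ndarray:
    """rFFT of the normalised spherical kernel rho, built wrap-centred at 0."""
    axes = []
    for n, v in zip(grid.shape, grid.voxel_size):
        x = np.fft.fftfreq(n) * n * v  # signed periodic distance in mm
        axes.append(x)
    x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)
    rho = (x**2 + y**2 + z**2 <= radius_mm**2 + 1e-9).astype(float)
    rho /= rho.sum()
    return spfft.rfftn(rho)


def sharp_filter(
    freq: ScalarVolume, mask: np.ndarray, params: SharpParams = SharpParams()
) -> tuple[ScalarVolume, np.ndarray]:
    """Remove background (harmonic) fields inside ``mask``.

    Returns the filtered frequency volume (zero outside the eroded mask, zero
    mean inside it) and the eroded mask itself.

    Raises
    ------
    ValueError
        If the mask is empty after erosion by the kernel radius.
    """
    grid = freq.grid
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match the frequency grid")

    mean_voxel = float(np.mean(grid.voxel_size))
    erosion_vox = params.erosion_vox
    if erosion_vox is None:
        erosion_vox = max(1.0, params.kernel_radius / mean_voxel)
    eroded = erode(mask, erosion_vox)
    if not eroded.any():
        raise ValueError(
            "mask vanished after erosion; enlarge the mask or shrink the kernel"
        )

    rho_hat = _smv_kernel_hat(grid, params.kernel_radius)
    smv_hat = 1.0 - rho_hat

    # forward SMV high-pass, confined to the eroded mask
    inner = spfft.irfftn(smv_hat * spfft.rfftn(freq.data * mask), s=grid.shape)
    inner *= eroded

    # TSVD deconvolution of (delta - rho)
    inv = np.zeros_like(smv_hat)
    keep = np.abs(smv_hat) > params.tsvd_threshold
    inv[keep] = 1.0 / smv_hat[keep]
    local = spfft.irfftn(inv * spfft.rfftn(inner), s=grid.shape).real
    local *= eroded
    local[eroded] -= local[eroded].mean()

    return ScalarVolume(local, grid, freq.units, eroded), eroded
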