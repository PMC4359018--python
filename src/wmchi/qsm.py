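"""Thresholded k-space division (TKD) dipole inversion.

QSM inverts the dipole convolution ``f = f0 * IFT{ D(k) FT{chi} }``.  Direct
division by D is ill-posed because D vanishes on the double cone at the magic
angle; TKD regularises by flooring the kernel magnitude at a threshold delta
before dividing.  Because flooring systematically shrinks the passband gain,
a global multiplicative correction — the reciprocal of the central value of
the point-spread function ``IFT{D * D_tkd^{-1}}`` — is applied to restore the
amplitude of compact sources.

Two inverse-kernel variants are provided:

* ``standard``: ``1/D`` where ``|D| >= delta``, ``sign(D)/delta`` in the
  truncation region (``+1/delta`` on the exact zero cone);
* ``fully_relaxed``: the constant ``+1/delta`` over the whole truncation
  region — the sign as well as the magnitude is relaxed, on the view that
  the sign of D is not meaningful close to the cone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft

from .forward import _crop, _iso_kernel_rfft, _pad
from .volumes import FieldContext, GridSpec, ScalarVolume

__all__ = ["TkdParams", "tkd_inverse_kernel", "tkd_correction_factor", "qsm_tkd"]


@dataclass(frozen=True)
class TkdParams:
    threshold: float = 0.07
    variant: str = "standard"
    apply_correction: bool = True

    def __post_init__(self):
        if not 0 < self.threshold < 2.0 / 3.0:
            raise ValueError("TKD threshold must lie in (0, 2/3)")
        if self.variant not in ("standard", "fully_relaxed"):
            raise ValueError(f"unknown TKD variant {self.variant!r}")


def _inverse_kernel_from_D(D: np.ndarray, params: TkdParams) -> np.ndarray:
    delta = params.threshold
    inv = np.empty_like(D)
    big = np.abs(D) >= delta
    inv[big] = 1.0 / D[big]
    small = ~big
    if params.variant == "standard":
        sign = np.where(D[small] >= 0.0, 1.0, -1.0)  # sign(0) := +1
        inv[small] = sign / delta
    else:  # fully relaxed: constant positive floor over the truncation region
        inv[small] = 1.0 / delta
    return inv


def tkd_inverse_kernel(
    grid: GridSpec, ctx: FieldContext, params: TkdParams = TkdParams(),
    padded: bool = False,
) -> np.ndarray:
    """Regularised inverse dipole kernel on the (optionally padded) k-grid."""
    from .forward import iso_kernel

    D = iso_kernel(grid, ctx, padded=padded)
    return _inverse_kernel_from_D(D, params)


def tkd_correction_factor(
    grid: GridSpec, ctx: FieldContext, params: TkdParams = TkdParams()
) -> float:
    """Global amplitude correction 1 / PSF(0) of the composite D * D_tkd^-1.

    The central PSF value is the k-space mean of ``D * D_tkd^{-1}``; it tends
    to 1 as delta -> 0 and grows monotonically with delta as a larger
    fraction of k-space is floored.
    """
    pshape = grid.padded_shape
    D = _iso_kernel_rfft(pshape, grid.voxel_size, ctx.h)
    inv = _inverse_kernel_from_D(D, params)
    prod = D * inv
    # mean over the full (hermitian) k-grid from the rfft half-spectrum
    nz = pshape[2]
    weights = np.full(prod.shape[2], 2.0)
    weights[0] = 1.0
    if nz % 2 == 0:
        weights[-1] = 1.0
    total = (prod * weights).sum()
    psf0 = total / np.prod(pshape)
    return float(1.0 / psf0)


def qsm_tkd(
    freq: ScalarVolume, ctx: FieldContext, params: TkdParams = TkdParams()
) -> ScalarVolume:
    """Susceptibility map (ppm) from a brain-masked, mean-referenced frequency map."""
    if freq.units != "Hz":
        raise ValueError(f"expected a frequency map in Hz, got {freq.units}")
    grid = freq.grid
    pshape = grid.padded_shape
    D = _iso_kernel_rfft(pshape, grid.voxel_size, ctx.h)
    inv = _inverse_kernel_from_D(D, params)
    chi_hat = inv * spfft.rfftn(_pad(freq.data / ctx.larmor_scale, pshape))
    chi = _crop(spfft.irfftn(chi_hat, s=pshape), grid.shape)
    if params.apply_correction:
        chi = chi * tkd_correction_factor(grid, ctx, params)
    if freq.mask is not None:
        chi = chi * freq.mask
    return ScalarVolume(chi, grid, "ppm", freq.mask)
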