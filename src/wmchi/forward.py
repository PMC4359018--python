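"""k-space forward field models.

The frequency perturbation measured by gradient-echo MRI around a
susceptibility distribution is, to first order, a convolution of the
distribution with the unit dipole response.  In the Fourier domain the
convolution is a pointwise product with the dipole kernel

    D(k) = 1/3 - (k . h)^2 / |k|^2,

where ``h`` is the unit B0 direction.  For a full symmetric susceptibility
tensor field ``X(r)`` the generalisation is

    f(k) = f0 * [ h^T X(k) h / 3  -  (k^T h)(k^T X(k) h) / |k|^2 ],

which reduces exactly to the scalar kernel for ``X = chi * I``.  The k = 0
term of every kernel is set to zero, i.e. computed fields are referenced to
the volume mean — this matches SHARP-filtered, mean-removed measured data.

All forward operators zero-pad by ``grid.pad_factor`` before transforming and
crop back, to suppress circular-convolution wrap-around.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as spfft

from .volumes import (
    FieldContext,
    GridSpec,
    ScalarVolume,
    SymmetricTensorVolume,
    cylsym_tensor,
    larmor_scale,
)

__all__ = [
    "larmor_scale",
    "iso_kernel",
    "simulate_iso_field",
    "cylsym_aniso_field",
    "tensor_forward",
    "dual_echo_maps",
    "axis_from_polar",
]


def _k_axes(shape, voxel, rfft: bool):
    """Sparse spatial-frequency axes (cycles/mm) for an FFT of ``shape``."""
    axes = [np.fft.fftfreq(n, d=v) for n, v in zip(shape, voxel)]
    if rfft:
        axes[-1] = np.fft.rfftfreq(shape[-1], d=voxel[-1])
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _kernel_fields(shape, voxel, h, rfft: bool):
    """Return (kh/|k|, unit k-vector components) with the k=0 entry zeroed."""
    kx, ky, kz = _k_axes(shape, voxel, rfft)
    k2 = kx**2 + ky**2 + kz**2
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_k = 1.0 / np.sqrt(k2)
    inv_k[0, 0, 0] = 0.0
    khx, khy, khz = kx * inv_k, ky * inv_k, kz * inv_k
    kh = khx * h[0] + khy * h[1] + khz * h[2]
    return kh, (khx, khy, khz)


def iso_kernel(grid: GridSpec, ctx: FieldContext, padded: bool = False) -> np.ndarray:
    """Discrete dipole kernel D(k) = 1/3 - (k.h)^2/|k|^2 with D(0) = 0."""
    shape = grid.padded_shape if padded else grid.shape
    kh, _ = _kernel_fields(shape, grid.voxel_size, ctx.h, rfft=False)
    D = 1.0 / 3.0 - kh**2
    D[0, 0, 0] = 0.0  # field referenced to the volume mean
    return D


def _iso_kernel_rfft(shape, voxel, h):
    kh, _ = _kernel_fields(shape, voxel, h, rfft=True)
    D = 1.0 / 3.0 - kh**2
    D[0, 0, 0] = 0.0
    return D


def _pad(data: np.ndarray, padded_shape) -> np.ndarray:
    if data.shape == tuple(padded_shape):
        return data
    out = np.zeros(padded_shape, dtype=data.dtype)
    out[tuple(slice(0, n) for n in data.shape)] = data
    return out


def _crop(data: np.ndarray, shape) -> np.ndarray:
    return data[tuple(slice(0, n) for n in shape)]


def simulate_iso_field(chi: ScalarVolume, ctx: FieldContext) -> ScalarVolume:
    """Frequency map (Hz) generated by an isotropic susceptibility map (ppm)."""
    if chi.units != "ppm":
        raise ValueError(f"isotropic forward model expects ppm input, got {chi.units}")
    grid = chi.grid
    pshape = grid.padded_shape
    chi_hat = spfft.rfftn(_pad(chi.data, pshape))
    D = _iso_kernel_rfft(pshape, grid.voxel_size, ctx.h)
    f = spfft.irfftn(D * chi_hat, s=pshape)
    f = _crop(f, grid.shape) * ctx.larmor_scale
    return ScalarVolume(f, grid, "Hz", chi.mask)


def tensor_forward(X: SymmetricTensorVolume, ctx: FieldContext) -> ScalarVolume:
    """Frequency map (Hz) of a full symmetric susceptibility tensor field (ppm)."""
    grid = X.grid
    pshape = grid.padded_shape
    h = ctx.h
    kh, (khx, khy, khz) = _kernel_fields(pshape, grid.voxel_size, h, rfft=True)

    # t_j(k) = sum_l X_hat_{jl}(k) h_l, accumulated one component at a time
    t = [None, None, None]
    pairs = {  # component name -> (j, l) index pairs it contributes to
        "xx": [(0, 0)], "yy": [(1, 1)], "zz": [(2, 2)],
        "xy": [(0, 1), (1, 0)], "xz": [(0, 2), (2, 0)], "yz": [(1, 2), (2, 1)],
    }
    from .volumes import TENSOR_COMPONENTS

    for idx, name in enumerate(TENSOR_COMPONENTS):
        comp = X.components[..., idx]
        if not comp.any():
            continue
        c_hat = spfft.rfftn(_pad(comp, pshape))
        for j, l in pairs[name]:
            contrib = c_hat * h[l]
            t[j] = contrib if t[j] is None else t[j] + contrib
    if all(tj is None for tj in t):
        return ScalarVolume(np.zeros(grid.shape), grid, "Hz")
    zero = np.zeros(pshape[:2] + (pshape[2] // 2 + 1,), dtype=complex)
    t = [zero if tj is None else tj for tj in t]

    ht = h[0] * t[0] + h[1] * t[1] + h[2] * t[2]
    kt = khx * t[0] + khy * t[1] + khz * t[2]
    f_hat = ht / 3.0 - kh * kt
    f_hat[0, 0, 0] = 0.0  # k = 0 of both parts referenced out
    f = _crop(spfft.irfftn(f_hat, s=pshape), grid.shape) * ctx.larmor_scale
    return ScalarVolume(f, grid, "Hz")


def axis_from_polar(theta_deg: float, phi_deg: float, ctx: FieldContext) -> np.ndarray:
    """Unit principal-axis vector at polar angle ``theta`` from B0.

    ``theta`` is the angle between the axis and B0; ``phi`` is the azimuth
    about B0 in a deterministic orthonormal frame built from the B0 vector.
    """
    h = ctx.h
    # deterministic complement basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, h)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, h) * h
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(h, e1)
    th, ph = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
    return np.cos(th) * h + np.sin(th) * (np.cos(ph) * e1 + np.sin(ph) * e2)


def cylsym_aniso_field(
    chi_aniso: ScalarVolume, axis, ctx: FieldContext
) -> ScalarVolume:
    """Field (Hz) of a zero-trace cylindrically symmetric tensor, uniform axis.

    ``axis`` is either a unit 3-vector in the lab frame or a ``(theta, phi)``
    pair in degrees relative to B0 (see :func:`axis_from_polar`).  The result
    equals :func:`tensor_forward` applied to
    ``chi_aniso * (3/2)(n n^T - I/3)`` but costs a single scalar FFT because
    the tensor direction is spatially uniform.
    """
    if chi_aniso.units != "ppm":
        raise ValueError(f"expected ppm input, got {chi_aniso.units}")
    n = np.asarray(axis, dtype=float)
    if n.shape == (2,):
        n = axis_from_polar(n[0], n[1], ctx)
    if n.shape != (3,):
        raise ValueError("axis must be a 3-vector or a (theta, phi) pair")
    if abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValueError("principal axis must be a unit vector")

    T = cylsym_tensor(0.0, 1.0, n)  # zero-trace unit-chi_A tensor
    grid = chi_aniso.grid
    pshape = grid.padded_shape
    h = ctx.h
    kh, (khx, khy, khz) = _kernel_fields(pshape, grid.voxel_size, h, rfft=True)
    Th = T @ h
    # scalar k-space factor: h^T T h / 3 - (k.h/|k|) (k^T T h / |k|)
    factor = (h @ Th) / 3.0 - kh * (khx * Th[0] + khy * Th[1] + khz * Th[2])
    factor[0, 0, 0] = 0.0
    c_hat = spfft.rfftn(_pad(chi_aniso.data, pshape))
    f = _crop(spfft.irfftn(factor * c_hat, s=pshape), grid.shape) * ctx.larmor_scale
    return ScalarVolume(f, grid, "Hz", chi_aniso.mask)


def dual_echo_maps(
    echo1: np.ndarray, echo2: np.ndarray, ctx: FieldContext, grid: GridSpec
) -> tuple[ScalarVolume, ScalarVolume]:
    """Frequency (Hz) and R2* (1/s) maps from two complex gradient echoes.

    Frequency is the echo-to-echo phase evolution over ``2 pi * dTE``; R2* is
    the log-magnitude decay rate.  Voxels with vanishing magnitude in either
    echo are flagged out in the returned masks instead of propagating
    infinities.
    """
    e1 = np.asarray(echo1, dtype=complex)
    e2 = np.asarray(echo2, dtype=complex)
    if e1.shape != e2.shape:
        raise ValueError("echo volumes must share a shape")
    dte = ctx.delta_te
    mag1, mag2 = np.abs(e1), np.abs(e2)
    valid = (mag1 > 0) & (mag2 > 0)

    dphi = np.zeros(e1.shape)
    dphi[valid] = np.angle((e2 * np.conj(e1))[valid])
    freq = dphi / (2.0 * np.pi * dte)

    r2s = np.zeros(e1.shape)
    r2s[valid] = (np.log(mag1[valid]) - np.log(mag2[valid])) / dte
    return (
        ScalarVolume(freq, grid, "Hz", valid),
        ScalarVolume(r2s, grid, "s^-1", valid),
    )
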