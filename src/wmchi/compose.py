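"""Compose brain frequency maps: bulk isotropic, bulk anisotropic, microstructure.

Three physically distinct contributions are assembled per B0 direction:

* ``f_I`` — nonlocal dipole field of the isotropic susceptibility map;
* ``f_A`` — nonlocal field of the zero-trace cylindrically symmetric
  anisotropy tensor, whose per-voxel principal axis follows the fiber field
  (evaluated with the general tensor forward model, which reduces to the
  uniform-axis kernel when the axis is constant);
* ``f_M`` — the *local* microstructure frequency offset
  ``A * FA_n * (sin^2 theta - 2/3) + b0`` inside white matter.  The -2/3
  makes the offset average to zero over a random fiber-orientation
  distribution, separating it from the orientation-independent offset b0.
  Microstructure is a property of how water samples the intra-voxel field, so
  it enters as a direct map, not as a field source.

Composites ``f_IA = f_I + f_A`` and ``f_IAM = f_I + f_A + f_M`` are the
inputs to the QSM/STI artifact experiments.  All maps are brain-masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft

from .forward import _crop, _kernel_fields, _pad
from .synthetic import BrainSusceptibilityModel, FA_REFERENCE
from .volumes import FieldContext, ScalarVolume, SymmetricTensorVolume

__all__ = [
    "MicrostructureParams",
    "fa_normalize",
    "fiber_angle_map",
    "micro_offset_map",
    "wm_anisotropy_tensor",
    "compose",
    "FieldSynthesizer",
]


@dataclass(frozen=True)
class MicrostructureParams:
    """Amplitude A (Hz, from the nerve experiment) and offset b0 (Hz)."""

    amplitude: float = -5.59
    b0_offset: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.amplitude) and np.isfinite(self.b0_offset)):
            raise ValueError("microstructure parameters must be finite")


def fa_normalize(fa: np.ndarray, ref: float = FA_REFERENCE) -> np.ndarray:
    """FA divided by the reference (optic-nerve) FA; deliberately unclipped."""
    if not ref > 0:
        raise ValueError("reference FA must be positive")
    return np.asarray(fa, dtype=float) / ref


def fiber_angle_map(fiber_dirs: np.ndarray, b0_direction) -> np.ndarray:
    """Angle (degrees, in [0, 90]) between each fiber and B0; axially symmetric.

    Zero fiber vectors yield NaN so they can be masked out.
    """
    h = np.asarray(b0_direction, dtype=float)
    h = h / np.linalg.norm(h)
    dirs = np.asarray(fiber_dirs, dtype=float)
    norms = np.linalg.norm(dirs, axis=-1)
    dot = np.abs(dirs @ h)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.clip(dot / norms, 0.0, 1.0)
    theta = np.degrees(np.arccos(cos))
    theta[norms == 0] = np.nan
    return theta


def micro_offset_map(
    params: MicrostructureParams,
    fa_n: np.ndarray,
    theta_deg: np.ndarray,
    wm_mask: np.ndarray,
    grid,
) -> ScalarVolume:
    """Local microstructure offset f_M = A * FA_n * (sin^2 theta - 2/3) + b0 in WM."""
    s2 = np.sin(np.deg2rad(theta_deg)) ** 2
    f_m = params.amplitude * fa_n * (s2 - 2.0 / 3.0) + params.b0_offset
    f_m = np.where(np.asarray(wm_mask, dtype=bool) & np.isfinite(f_m), f_m, 0.0)
    return ScalarVolume(f_m, grid, "Hz", np.asarray(wm_mask, dtype=bool))


def wm_anisotropy_tensor(model: BrainSusceptibilityModel) -> SymmetricTensorVolume:
    """Zero-trace anisotropy tensor field chi_A * (3/2)(v v^T - I/3) over WM."""
    v = model.fiber_dirs
    chi_a = model.chi_aniso.data
    comps = np.zeros(model.grid.shape + (6,))
    prods = [
        v[..., 0] * v[..., 0], v[..., 1] * v[..., 1], v[..., 2] * v[..., 2],
        v[..., 0] * v[..., 1], v[..., 0] * v[..., 2], v[..., 1] * v[..., 2],
    ]
    for k, p in enumerate(prods):
        comps[..., k] = 1.5 * chi_a * p
    for k in range(3):
        comps[..., k] -= 0.5 * chi_a  # subtract chi_A * (3/2) * (1/3) on diagonal
    comps[~model.wm_mask] = 0.0
    return SymmetricTensorVolume(comps, model.grid)


class FieldSynthesizer:
    """Caches the k-space spectra of a brain model to compose fields quickly
    for many B0 directions (the spectra do not depend on orientation)."""

    def __init__(self, model: BrainSusceptibilityModel, b0_strength: float = 7.0):
        self.model = model
        self.b0_strength = b0_strength
        grid = model.grid
        self._pshape = grid.padded_shape
        self._chi_iso_hat = spfft.rfftn(_pad(model.chi_iso.data, self._pshape))
        tensor = wm_anisotropy_tensor(model)
        self._tensor_hats = [
            spfft.rfftn(_pad(tensor.components[..., k], self._pshape))
            for k in range(6)
        ]

    def fields(
        self,
        b0_direction,
        micro: MicrostructureParams | None = None,
    ) -> dict[str, ScalarVolume]:
        """Component maps f_I, f_A, f_M and composites for one B0 direction."""
        model, grid = self.model, self.model.grid
        ctx = FieldContext((0.0, 0.0, 1.0), self.b0_strength).with_direction(
            b0_direction
        )
        h = ctx.h
        pshape = self._pshape
        kh, (khx, khy, khz) = _kernel_fields(pshape, grid.voxel_size, h, rfft=True)

        D = 1.0 / 3.0 - kh**2
        D[0, 0, 0] = 0.0
        f_i = _crop(spfft.irfftn(D * self._chi_iso_hat, s=pshape), grid.shape)
        f_i = f_i * ctx.larmor_scale

        # tensor forward: t_j = sum_l X_hat_jl h_l with symmetric components
        hx, hy, hz = h
        cxx, cyy, czz, cxy, cxz, cyz = self._tensor_hats
        tx = cxx * hx + cxy * hy + cxz * hz
        ty = cxy * hx + cyy * hy + cyz * hz
        tz = cxz * hx + cyz * hy + czz * hz
        ht = hx * tx + hy * ty + hz * tz
        kt = khx * tx + khy * ty + khz * tz
        fa_hat = ht / 3.0 - kh * kt
        fa_hat[0, 0, 0] = 0.0
        f_a = _crop(spfft.irfftn(fa_hat, s=pshape), grid.shape)
        f_a = f_a * ctx.larmor_scale

        micro = micro or MicrostructureParams()
        theta = fiber_angle_map(model.fiber_dirs, h)
        fa_n = fa_normalize(model.fa.data)
        f_m = micro_offset_map(micro, fa_n, theta, model.wm_mask, grid).data

        brain = model.brain_mask
        out = {}
        for name, data in (
            ("f_I", f_i),
            ("f_A", f_a),
            ("f_M", f_m),
            ("f_IA", f_i + f_a),
            ("f_IAM", f_i + f_a + f_m),
        ):
            out[name] = ScalarVolume(data * brain, grid, "Hz", brain)
        return out


def compose(
    model: BrainSusceptibilityModel,
    ctx: FieldContext,
    include: set[str] = frozenset({"iso", "aniso", "micro"}),
    params: MicrostructureParams = MicrostructureParams(),
) -> dict[str, ScalarVolume]:
    """Named component and composite frequency maps for one B0 direction.

    ``include`` selects which physical contributions are computed; excluded
    components are returned as zero maps so composites remain well defined.
    Requesting the anisotropic component requires the model's fiber field.
    """
    if "aniso" in include and not np.any(model.fiber_dirs):
        raise ValueError("anisotropic component requested but fiber field is empty")
    synth = FieldSynthesizer(model, ctx.b0_strength)
    fields = synth.fields(ctx.h, params)
    zero = ScalarVolume(
        np.zeros(model.grid.shape), model.grid, "Hz", model.brain_mask
    )
    if "iso" not in include:
        fields["f_I"] = zero
    if "aniso" not in include:
        fields["f_A"] = zero
    if "micro" not in include:
        fields["f_M"] = zero
    f_ia = fields["f_I"].data + fields["f_A"].data
    fields["f_IA"] = ScalarVolume(f_ia, model.grid, "Hz", model.brain_mask)
    fields["f_IAM"] = ScalarVolume(
        f_ia + fields["f_M"].data, model.grid, "Hz", model.brain_mask
    )
    return fields
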