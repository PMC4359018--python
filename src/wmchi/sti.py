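"""Susceptibility tensor imaging: multi-orientation forward model and inversion.

With frequency maps acquired at several B0 orientations, the six unique
components of a symmetric susceptibility tensor per voxel become estimable.
In k-space the forward model is linear and *local in k*: for orientation i
with unit direction h_i,

    f_i(k) / f0 = sum_m  a_{i,m}(k) X_m(k),

where the six real coefficients a_{i,m} derive from the tensor dipole kernel
``h^T X h / 3 - (k^T h)(k^T X h)/|k|^2``.  The inversion solves the stacked
least-squares system over all orientations by conjugate-gradient iteration on
the normal equations (which are 6x6 and Hermitian positive semidefinite at
each k), with an iteration cap of 30 that in practice dominates the
tolerance.  The k = 0 component is unobservable and fixed to zero, so the
reconstructed component maps are mean-referenced.

Eigen-analysis converts the tensor field into the scalar maps practitioners
inspect: the isotropic susceptibility (mean eigenvalue), the anisotropy
(eigenvalue most different from the mean, minus the mean — a convention that
returns exactly chi_A for tensors built as chi_I*I + chi_A*(3/2)(nn^T-I/3))
and the principal eigenvector (PEV), the tensor-based fiber-direction
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as spfft

from .forward import _crop, _kernel_fields, _pad
from .volumes import (
    FieldContext,
    ScalarVolume,
    SymmetricTensorVolume,
    TENSOR_COMPONENTS,
)

__all__ = [
    "StiSolveParams",
    "sti_forward",
    "sti_invert",
    "tensor_eigen",
    "TensorEigenResult",
    "angle_error_map",
]


@dataclass(frozen=True)
class StiSolveParams:
    max_iterations: int = 30
    tolerance: float = 1e-6

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("need at least one iteration")


def _orientation_coeffs(pshape, voxel, h):
    """Six real coefficient fields a_m(k) for one orientation (rfft grid)."""
    kh, (khx, khy, khz) = _kernel_fields(pshape, voxel, h, rfft=True)
    khat = (khx, khy, khz)
    coeffs = []
    idx = {"xx": (0, 0), "yy": (1, 1), "zz": (2, 2),
           "xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}
    for name in TENSOR_COMPONENTS:
        i, j = idx[name]
        if i == j:
            a = h[i] * h[j] / 3.0 - kh * (khat[i] * h[j])
        else:
            # symmetric off-diagonal components appear twice in the tensor
            a = 2.0 * h[i] * h[j] / 3.0 - kh * (khat[i] * h[j] + khat[j] * h[i])
        a = np.asarray(np.broadcast_to(a, kh.shape)).copy()
        a[0, 0, 0] = 0.0  # DC is unobservable; components are mean-referenced
        coeffs.append(a)
    return coeffs


def sti_forward(
    X: SymmetricTensorVolume, orientations, ctx: FieldContext
) -> list[ScalarVolume]:
    """Frequency maps (Hz) of a tensor field at each B0 orientation."""
    from .forward import tensor_forward

    out = []
    for h in np.atleast_2d(np.asarray(orientations, dtype=float)):
        out.append(tensor_forward(X, ctx.with_direction(h)))
    return out


def sti_invert(
    freqs: list[ScalarVolume],
    orientations,
    ctx: FieldContext,
    params: StiSolveParams = StiSolveParams(),
    mask: np.ndarray | None = None,
) -> SymmetricTensorVolume:
    """Least-squares tensor reconstruction from multi-orientation frequency maps.

    With ``mask=None`` the data are trusted everywhere and the normal
    equations decouple per k, so the conjugate-gradient solve converges
    rapidly towards the exact per-k least-squares tensor.  With a ``mask``
    (e.g. a brain mask, for data that only exist inside the head) the
    data-fidelity term is restricted to masked voxels in image space; the
    operator then couples k-space points and the 30-iteration cap genuinely
    limits convergence, as it did in the processing this reproduces.

    Fewer than six orientations cannot determine all six components; the
    solve still runs (conjugate gradients returns the minimum-norm
    least-squares iterate) but a rank warning is raised.
    """
    orientations = np.atleast_2d(np.asarray(orientations, dtype=float))
    if len(freqs) != len(orientations):
        raise ValueError("one frequency map per orientation required")
    if len(orientations) < 6:
        import warnings

        warnings.warn(
            "fewer than 6 orientations: tensor solution is rank deficient",
            RuntimeWarning,
        )
    if mask is not None:
        return _sti_invert_masked(freqs, orientations, ctx, params, mask)
    grid = freqs[0].grid
    pshape = grid.padded_shape
    voxel = grid.voxel_size
    rshape = pshape[:2] + (pshape[2] // 2 + 1,)

    # accumulate the 6x6 normal operator and the right-hand side over orientations
    normal = np.zeros((6, 6) + rshape)
    rhs = np.zeros((6,) + rshape, dtype=complex)
    for h, f in zip(orientations, freqs):
        h = h / np.linalg.norm(h)
        coeffs = _orientation_coeffs(pshape, voxel, h)
        f_hat = spfft.rfftn(_pad(f.data / ctx.larmor_scale, pshape))
        for m in range(6):
            rhs[m] += coeffs[m] * f_hat
            for mm in range(m, 6):
                normal[m, mm] += coeffs[m] * coeffs[mm]
    for m in range(6):
        for mm in range(m + 1, 6):
            normal[mm, m] = normal[m, mm]

    def apply(u):
        return np.einsum("mn...,n...->m...", normal, u)

    def inner(a, b):
        return float(np.real(np.vdot(a, b)))

    # conjugate gradients on the (block-diagonal) normal equations
    u = np.zeros_like(rhs)
    r = rhs - apply(u)
    p = r.copy()
    rs = inner(r, r)
    rs0 = rs
    for _ in range(params.max_iterations):
        if rs <= params.tolerance**2 * rs0 or rs == 0.0:
            break
        Ap = apply(p)
        alpha = rs / inner(p, Ap)
        u += alpha * p
        r -= alpha * Ap
        rs_new = inner(r, r)
        p = r + (rs_new / rs) * p
        rs = rs_new

    comps = np.stack(
        [_crop(spfft.irfftn(u[m], s=pshape), grid.shape) for m in range(6)], axis=-1
    )
    return SymmetricTensorVolume(comps, grid)


def _sti_invert_masked(freqs, orientations, ctx, params, mask):
    """CGNR with the data mask inside the forward operator (image space)."""
    grid = freqs[0].grid
    pshape = grid.padded_shape
    voxel = grid.voxel_size
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match the frequency grid")
    pmask = _pad(mask.astype(float), pshape)

    coeffs = []
    for h in orientations:
        h = h / np.linalg.norm(h)
        coeffs.append(_orientation_coeffs(pshape, voxel, h))

    data = [pmask * _pad(f.data / ctx.larmor_scale, pshape) for f in freqs]

    def forward(u):
        """u: (6,) padded real image-space components -> masked fields per orientation."""
        u_hat = [spfft.rfftn(u[m]) for m in range(6)]
        out = []
        for cs in coeffs:
            f_hat = cs[0] * u_hat[0]
            for m in range(1, 6):
                f_hat = f_hat + cs[m] * u_hat[m]
            out.append(pmask * spfft.irfftn(f_hat, s=pshape))
        return out

    def adjoint(fields):
        acc = [None] * 6
        for cs, f in zip(coeffs, fields):
            f_hat = spfft.rfftn(pmask * f)
            for m in range(6):
                term = cs[m] * f_hat
                acc[m] = term if acc[m] is None else acc[m] + term
        return np.stack([spfft.irfftn(a, s=pshape) for a in acc])

    u = np.zeros((6,) + pshape)
    r = adjoint(data)  # rhs - N @ 0
    p = r.copy()
    rs = float((r * r).sum())
    rs0 = rs
    for _ in range(params.max_iterations):
        if rs == 0.0 or rs <= params.tolerance**2 * rs0:
            break
        Np = adjoint(forward(p))
        alpha = rs / float((p * Np).sum())
        u += alpha * p
        r -= alpha * Np
        rs_new = float((r * r).sum())
        p = r + (rs_new / rs) * p
        rs = rs_new

    comps = np.stack([_crop(u[m], grid.shape) for m in range(6)], axis=-1)
    comps = comps - comps.reshape(-1, 6).mean(axis=0)
    return SymmetricTensorVolume(comps, grid)


@dataclass
class TensorEigenResult:
    """Per-voxel eigen-analysis of a symmetric susceptibility tensor field."""

    eigenvalues: np.ndarray  # shape + (3,), ascending
    chi_iso: ScalarVolume  # mean eigenvalue (ppm)
    chi_aniso: ScalarVolume  # eigenvalue most different from the mean, minus it
    pev: np.ndarray  # shape + (3,), unit vectors, z >= 0
    defined: np.ndarray = field(default=None)  # where the PEV is meaningful

    def angle_error(self, truth_dirs: np.ndarray, mask: np.ndarray):
        return angle_error_map(self.pev, truth_dirs, mask & self.defined)


def tensor_eigen(
    X: SymmetricTensorVolume, mask: np.ndarray | None = None,
    degenerate_tol: float = 1e-12,
) -> TensorEigenResult:
    """Eigendecompose the tensor field voxelwise.

    ``chi_aniso`` is ``lambda_dif - chi_iso`` with ``lambda_dif`` the
    eigenvalue of largest absolute deviation from the mean; for isotropic
    (degenerate) voxels it is 0 and the PEV is flagged undefined.
    """
    grid = X.grid
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    mats = X.as_matrix_field()[mask]
    if not np.all(np.isfinite(mats)):
        raise ValueError("non-finite tensor components inside the mask")
    w, v = np.linalg.eigh(mats)  # ascending eigenvalues, columns are vectors

    mean = w.mean(axis=-1)
    dev = w - mean[:, None]
    pick = np.argmax(np.abs(dev), axis=-1)
    rows = np.arange(w.shape[0])
    lam_dif = w[rows, pick]
    aniso = lam_dif - mean
    pev = v[rows, :, pick]

    degenerate = np.abs(aniso) <= degenerate_tol
    aniso[degenerate] = 0.0
    pev[degenerate] = 0.0
    # axial quantity: fix the sign so the z component is non-negative
    flip = pev[:, 2] < 0
    pev[flip] *= -1.0

    evals = np.zeros(grid.shape + (3,))
    evals[mask] = w
    chi_iso = np.zeros(grid.shape)
    chi_iso[mask] = mean
    chi_aniso = np.zeros(grid.shape)
    chi_aniso[mask] = aniso
    pev_field = np.zeros(grid.shape + (3,))
    pev_field[mask] = pev
    defined = np.zeros(grid.shape, dtype=bool)
    defined[mask] = ~degenerate

    return TensorEigenResult(
        eigenvalues=evals,
        chi_iso=ScalarVolume(chi_iso, grid, "ppm", mask),
        chi_aniso=ScalarVolume(chi_aniso, grid, "ppm", mask),
        pev=pev_field,
        defined=defined,
    )


def angle_error_map(
    pev: np.ndarray, truth_dirs: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Axial angle (degrees, [0, 90]) between estimated and true fiber axes.

    Returns the per-voxel angle map (NaN outside the mask / at undefined
    voxels) and a summary dict with the mean, SD and counts over valid
    voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    p = np.asarray(pev, dtype=float)
    t = np.asarray(truth_dirs, dtype=float)
    pn = np.linalg.norm(p, axis=-1)
    tn = np.linalg.norm(t, axis=-1)
    valid = mask & (pn > 0) & (tn > 0)
    dot = np.abs(np.sum(p * t, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.clip(dot / (pn * tn), 0.0, 1.0)
    angles = np.full(mask.shape, np.nan)
    angles[valid] = np.degrees(np.arccos(cos[valid]))
    summary = {
        "mean_deg": float(np.nanmean(angles[valid])) if valid.any() else np.nan,
        "sd_deg": float(np.nanstd(angles[valid])) if valid.any() else np.nan,
        "n_valid": int(valid.sum()),
        "n_excluded": int((mask & ~valid).sum()),
    }
    return angles, summary
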