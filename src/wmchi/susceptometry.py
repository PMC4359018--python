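"""Bulk susceptometry from the external field, and the residual orientation model.

The bulk isotropic (chi_I) and anisotropic (chi_A) susceptibility of an
embedded sample are estimated by regressing the measured frequency values in a
shell *outside* the sample onto the simulated unit-response fields of the
isotropic and zero-trace anisotropic forward models, jointly over all
acquisition orientations:

    f_meas(r, orientation) ~ chi_I * F_I(r, orientation) + chi_A * F_A(r, orientation)

Restricting the fit to the external shell makes it insensitive to exchange and
microstructure effects, which only shift frequencies inside the sample.  The
frequency left unexplained by the fitted bulk model *inside* the sample — the
residual frequency f_R — is then summarised per orientation and modelled as

    f_R(theta) = A * sin^2(theta) + b,

the phenomenological signature of orientation-dependent microstructure effects
(amplitude A) on top of an orientation-independent offset b.

Both fits are exposed as model classes whose ``fit()`` returns a results
object carrying estimates, standard errors and a ``summary()`` table, in the
style of statsmodels.  Estimation uses orthogonal-decomposition least squares
(numpy ``lstsq``); standard errors follow the classical linear-model
covariance ``sigma^2 (G^T G)^{-1}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .morphology import dilate, erode
from .volumes import ScalarVolume

__all__ = [
    "shell_mask",
    "fit_qualify",
    "residual_map",
    "roi_mean_residual",
    "nested_f_test",
    "BulkSusceptometry",
    "BulkSusceptometryResults",
    "OrientationResidualModel",
    "OrientationResidualResults",
]


# ---------------------------------------------------------------------------
# masks and residual maps


def shell_mask(sample_mask: np.ndarray, dilate_out: float = 8, dilate_in: float = 1):
    """External fitting shell: dilate(M, out) minus dilate(M, in).

    The inner dilation keeps a one-voxel guard band around the sample so that
    no voxel contaminated by internal (microstructure/exchange) offsets enters
    the external-field fit.
    """
    sample_mask = np.asarray(sample_mask, dtype=bool)
    if not sample_mask.any():
        raise ValueError("sample mask is empty")
    if dilate_out < dilate_in:
        raise ValueError("outer dilation must be at least the inner dilation")
    outer = dilate(sample_mask, dilate_out)
    inner = dilate(sample_mask, dilate_in)
    return outer & ~inner


def fit_qualify(shell: np.ndarray, r2star: ScalarVolume, r2star_max: float = 15.0):
    """Drop shell voxels with R2* at or above ``r2star_max`` (air bubbles etc.)."""
    shell = np.asarray(shell, dtype=bool)
    if r2star.data.shape != shell.shape:
        raise ValueError("R2* map and shell must share a grid")
    return shell & (r2star.data < r2star_max)


def residual_map(meas: ScalarVolume, sim_fitted: ScalarVolume) -> ScalarVolume:
    """Voxelwise measured-minus-fitted frequency."""
    if meas.data.shape != sim_fitted.data.shape:
        raise ValueError("volumes must share a grid")
    if meas.units != sim_fitted.units:
        raise ValueError("units mismatch between measured and simulated volumes")
    return meas.with_data(meas.data - sim_fitted.data)


def roi_mean_residual(
    f_r: ScalarVolume, sample_mask: np.ndarray, erode_vox: float = 1
) -> tuple[float, float]:
    """Mean and population SD of the residual inside the eroded sample mask."""
    roi = erode(np.asarray(sample_mask, dtype=bool), erode_vox)
    if not roi.any():
        raise ValueError("erosion emptied the sample mask")
    vals = f_r.data[roi]
    return float(vals.mean()), float(vals.std())


# ---------------------------------------------------------------------------
# bulk chi fit


class BulkSusceptometry:
    """Least-squares model for bulk (chi_I, chi_A) from external-field data.

    Parameters
    ----------
    measured, unit_iso, unit_aniso : sequences of ScalarVolume
        One measured frequency map (Hz) and the two unit-susceptibility
        response maps (Hz/ppm) per acquisition orientation, all processed
        (e.g. SHARP-filtered) identically.
    mask : boolean array
        Fit voxels (typically the qualified external shell), shared across
        orientations.
    """

    def __init__(self, measured, unit_iso, unit_aniso, mask):
        if not (len(measured) == len(unit_iso) == len(unit_aniso)):
            raise ValueError("one measured and two unit volumes per orientation")
        if len(measured) == 0:
            raise ValueError("at least one orientation is required")
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("fit mask is empty")
        self.n_orientations = len(measured)
        self.mask = mask
        self.endog = np.concatenate([m.data[mask] for m in measured])
        self.exog = np.column_stack(
            [
                np.concatenate([u.data[mask] for u in unit_iso]),
                np.concatenate([u.data[mask] for u in unit_aniso]),
            ]
        )
        self.n_voxels = int(mask.sum())

    def fit(self, isotropic_only: bool = False) -> "BulkSusceptometryResults":
        G = self.exog[:, :1] if isotropic_only else self.exog
        if np.linalg.matrix_rank(G) < G.shape[1]:
            raise np.linalg.LinAlgError(
                "rank-deficient design: the orientation set does not separate "
                "isotropic and anisotropic responses"
            )
        coef, _, _, _ = np.linalg.lstsq(G, self.endog, rcond=None)
        resid = self.endog - G @ coef
        rss = float(resid @ resid)
        n, p = G.shape
        sigma2 = rss / (n - p)
        cov = sigma2 * np.linalg.inv(G.T @ G)
        return BulkSusceptometryResults(self, coef, cov, rss, n, p, isotropic_only)


@dataclass
class BulkSusceptometryResults:
    """Fitted bulk susceptibilities with classical linear-model uncertainties."""

    model: BulkSusceptometry
    _coef: np.ndarray
    cov_params: np.ndarray
    rss: float
    nobs: int
    df_model: int
    isotropic_only: bool

    @property
    def chi_iso(self) -> float:
        return float(self._coef[0])

    @property
    def chi_aniso(self) -> float:
        return 0.0 if self.isotropic_only else float(self._coef[1])

    @property
    def params(self) -> pd.Series:
        names = ["chi_iso"] if self.isotropic_only else ["chi_iso", "chi_aniso"]
        return pd.Series(self._coef, index=names, name="ppm")

    @property
    def bse(self) -> pd.Series:
        se = np.sqrt(np.diag(self.cov_params))
        return pd.Series(se, index=self.params.index, name="ppm")

    @property
    def param_correlation(self) -> float:
        """Off-diagonal correlation between chi_I and chi_A estimates."""
        if self.isotropic_only:
            return 0.0
        d = np.sqrt(np.diag(self.cov_params))
        return float(self.cov_params[0, 1] / (d[0] * d[1]))

    @property
    def df_resid(self) -> int:
        return self.nobs - self.df_model

    def predict(self, unit_iso: ScalarVolume, unit_aniso: ScalarVolume) -> ScalarVolume:
        """Fitted frequency map chi_I*F_I + chi_A*F_A for one orientation."""
        data = self.chi_iso * unit_iso.data + self.chi_aniso * unit_aniso.data
        return ScalarVolume(data, unit_iso.grid, "Hz")

    def compare_f_test(self, reduced: "BulkSusceptometryResults"):
        """Nested F-test of this (full) fit against a reduced fit."""
        return nested_f_test(
            reduced.rss, reduced.df_model, self.rss, self.df_model, self.nobs
        )

    def summary(self) -> str:
        lines = ["Bulk susceptometry (external-field least squares)"]
        lines.append(
            f"  orientations: {self.model.n_orientations}   "
            f"fit voxels/orientation: {self.model.n_voxels}   nobs: {self.nobs}"
        )
        for name in self.params.index:
            lines.append(
                f"  {name:>9s} = {self.params[name]: .5f} +/- "
                f"{self.bse[name]:.5f} ppm"
            )
        if not self.isotropic_only:
            lines.append(f"  parameter correlation R = {self.param_correlation:.3f}")
        lines.append(f"  residual sum of squares = {self.rss:.4g} Hz^2")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# orientation model


class OrientationResidualModel:
    """Least-squares model f_R(theta) = A sin^2(theta) + b.

    ``theta_deg`` are fiber-to-field angles in degrees (axially symmetric, so
    theta and 180 - theta are equivalent; sin^2 enforces this).  ``weights``
    are optional inverse-variance weights; the default is ordinary least
    squares.
    """

    def __init__(self, theta_deg, f_r, weights=None):
        theta = np.asarray(theta_deg, dtype=float)
        y = np.asarray(f_r, dtype=float)
        if theta.shape != y.shape or theta.ndim != 1:
            raise ValueError("theta and residual values must be matching 1-D arrays")
        if np.unique(np.round(np.sin(np.deg2rad(theta)) ** 2, 12)).size < 2:
            raise np.linalg.LinAlgError(
                "all angles are equivalent; the model is rank deficient"
            )
        self.theta_deg = theta
        self.endog = y
        self.exog = np.column_stack([np.sin(np.deg2rad(theta)) ** 2, np.ones_like(y)])
        self.weights = None if weights is None else np.asarray(weights, dtype=float)

    def fit(self) -> "OrientationResidualResults":
        G, y = self.exog, self.endog
        if self.weights is not None:
            w = np.sqrt(self.weights)
            G, y = G * w[:, None], y * w
        coef, _, _, _ = np.linalg.lstsq(G, y, rcond=None)
        resid = y - G @ coef
        rss = float(resid @ resid)
        n, p = G.shape
        if n > p:
            cov = rss / (n - p) * np.linalg.inv(G.T @ G)
        else:  # exactly determined: interpolation, no error estimate
            cov = np.zeros((p, p))
        return OrientationResidualResults(self, coef, cov, rss, n)


@dataclass
class OrientationResidualResults:
    model: OrientationResidualModel
    _coef: np.ndarray
    cov_params: np.ndarray
    rss: float
    nobs: int

    @property
    def amplitude(self) -> float:
        """A: parallel-to-perpendicular swing of the residual frequency (Hz)."""
        return float(self._coef[0])

    @property
    def offset(self) -> float:
        """b: orientation-independent residual offset (Hz)."""
        return float(self._coef[1])

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._coef, index=["A", "b"], name="Hz")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=["A", "b"], name="Hz")

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.exog @ self._coef

    def predict(self, theta_deg) -> np.ndarray:
        s2 = np.sin(np.deg2rad(np.asarray(theta_deg, dtype=float))) ** 2
        return self.amplitude * s2 + self.offset

    def summary(self) -> str:
        return (
            "Residual orientation model f_R = A sin^2(theta) + b\n"
            f"  A = {self.amplitude: .3f} +/- {self.bse['A']:.3f} Hz\n"
            f"  b = {self.offset: .3f} +/- {self.bse['b']:.3f} Hz\n"
            f"  rss = {self.rss:.4g} Hz^2 over {self.nobs} orientations"
        )

    def plot(self, ax=None):
        """Residual means against angle with the fitted sin^2 curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        th = np.linspace(0, 90, 181)
        ax.plot(self.model.theta_deg, self.model.endog, "ko", label="ROI means")
        ax.plot(th, self.predict(th), "b-", label="A sin^2(theta) + b")
        ax.set_xlabel("angle to B0 (deg)")
        ax.set_ylabel("residual frequency (Hz)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# model comparison


def nested_f_test(rss_reduced, p_reduced, rss_full, p_full, n):
    """F-test for nested linear models.

    Returns ``(F, p)`` where ``F = ((rss_r - rss_f)/(p_f - p_r)) /
    (rss_f/(n - p_f))`` and ``p`` is the upper tail of the F(p_f - p_r,
    n - p_f) distribution.
    """
    if p_full <= p_reduced:
        raise ValueError("the full model must have more parameters")
    if n <= p_full:
        raise ValueError("need more observations than full-model parameters")
    if rss_full < 0 or rss_reduced < rss_full:
        raise ValueError("need rss_reduced >= rss_full >= 0")
    df1 = p_full - p_reduced
    df2 = n - p_full
    if rss_full == 0:
        return np.inf if rss_reduced > 0 else 0.0, 0.0 if rss_reduced > 0 else 1.0
    f_stat = ((rss_reduced - rss_full) / df1) / (rss_full / df2)
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return float(f_stat), p_value
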