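"""Synthetic inputs: the nerve-in-sphere phantom and a digitized brain model.

The pipeline was designed around two physical objects that cannot be shipped
as data: a spherical agarose phantom containing a short cylindrical section of
optic nerve imaged at ~10 orientations to B0, and a whole-brain
susceptibility model (white-matter mask, smoothly varying fiber orientations,
an FA map and deep grey-matter structures with literature susceptibility
values).  This module generates both from scratch, deterministically from a
seed, with the geometric and statistical structure the downstream analysis
assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .forward import cylsym_aniso_field, simulate_iso_field
from .morphology import erode
from .volumes import FieldContext, GridSpec, ScalarVolume

__all__ = [
    "NervePhantomSpec",
    "NervePhantomOrientation",
    "NervePhantom",
    "make_nerve_phantom",
    "BrainSusceptibilityModel",
    "make_brain_model",
    "hemisphere_orientations",
    "ten_orientation_angles",
    "add_noise",
]


def ten_orientation_angles() -> np.ndarray:
    """The ten nerve-to-field angles, 0 to 90 degrees in even 10-degree steps."""
    return np.arange(0.0, 91.0, 10.0)


def hemisphere_orientations(n: int = 16, seed: int | None = None) -> np.ndarray:
    """``n`` quasi-uniform unit B0 directions on the upper hemisphere.

    Deterministic Fibonacci-spiral construction (``seed`` is accepted for API
    symmetry with the stochastic generators but has no effect).  At least six
    well-spread directions are needed to make the six-component tensor
    inversion full rank.
    """
    if n < 6:
        raise ValueError("need at least 6 orientations for tensor inversion")
    i = np.arange(n)
    z = (i + 0.5) / n  # strictly positive: upper hemisphere
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def add_noise(vol: ScalarVolume, sd: float, seed: int) -> ScalarVolume:
    """Add i.i.d. Gaussian noise of standard deviation ``sd`` (seeded)."""
    if sd < 0:
        raise ValueError("noise SD must be non-negative")
    if sd == 0:
        return vol.with_data(vol.data.copy())
    rng = np.random.default_rng(seed)
    return vol.with_data(vol.data + rng.normal(0.0, sd, vol.data.shape))


# ---------------------------------------------------------------------------
# nerve-in-sphere phantom


@dataclass(frozen=True)
class NervePhantomSpec:
    """Geometry, ground truth and acquisition plan for the nerve phantom.

    Defaults are the desk-scale analogue of the physical phantom: a sphere of
    gel (radius 40 mm on a 96^3 grid of 1 mm voxels) holding a cylindrical
    nerve (radius 2.5 mm, length 20 mm) whose bulk susceptibilities are the
    optic-nerve estimates, with a uniform orientation-dependent residual
    offset injected inside the nerve.
    """

    grid: GridSpec = GridSpec((96, 96, 96), (1.0, 1.0, 1.0), pad_factor=2.0)
    sphere_radius: float = 40.0
    nerve_radius: float = 2.5
    nerve_length: float = 20.0
    chi_iso_true: float = -0.08152
    chi_aniso_true: float = 0.01128
    residual_amplitude: float = -5.59
    residual_offset: float = 4.88
    angles_deg: tuple[float, ...] = tuple(ten_orientation_angles())
    noise_sd: float = 0.0
    n_bubbles: int = 12
    bubble_r2star: float = 50.0
    gel_r2star: float = 5.0
    nerve_r2star: float = 20.0
    b0_strength: float = 7.0
    seed: int = 0

    def __post_init__(self):
        half_diag = np.hypot(self.nerve_length / 2.0, self.nerve_radius)
        if half_diag >= self.sphere_radius:
            raise ValueError("nerve does not fit inside the sphere")
        fov = min(n * v for n, v in zip(self.grid.shape, self.grid.voxel_size))
        if 2 * self.sphere_radius >= fov:
            raise ValueError("sphere does not fit inside the field of view")
        if any(not 0 <= a <= 90 for a in self.angles_deg):
            raise ValueError("angles must lie in [0, 90] degrees")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass
class NervePhantomOrientation:
    """Per-orientation volumes of the synthetic phantom."""

    angle_deg: float
    b0_direction: np.ndarray
    unit_iso: ScalarVolume  # Hz per ppm of chi_I
    unit_aniso: ScalarVolume  # Hz per ppm of chi_A
    f_true: ScalarVolume  # bulk forward field only
    f_meas: ScalarVolume  # + internal residual + noise
    r2star: ScalarVolume


@dataclass
class NervePhantom:
    spec: NervePhantomSpec
    nerve_mask: np.ndarray
    sphere_mask: np.ndarray
    orientations: list[NervePhantomOrientation] = field(default_factory=list)

    @property
    def grid(self) -> GridSpec:
        return self.spec.grid


def make_nerve_phantom(spec: NervePhantomSpec = NervePhantomSpec()) -> NervePhantom:
    """Simulate the multi-orientation phantom acquisition.

    For each angle theta the B0 direction is tilted by theta from the nerve
    axis (the z axis of the sample frame; volumes are never resampled).  The
    bulk field is ``chi_I * F_I + chi_A * F_A`` built from the two unit
    forward models; a spatially uniform residual ``A sin^2(theta) + b`` is
    injected inside the nerve mask eroded by one voxel (microstructure and
    exchange shift frequencies only inside the tissue); seeded Gaussian noise
    is then added.  A matching R2* volume is emitted with low gel values and
    a few seeded high-R2* "air bubble" voxels for exercising the R2*
    exclusion rule.
    """
    grid = spec.grid
    x, y, z = grid.coords()
    sphere = (x**2 + y**2 + z**2) <= spec.sphere_radius**2
    nerve = ((x**2 + y**2) <= spec.nerve_radius**2) & (
        np.abs(z + 0 * x + 0 * y) <= spec.nerve_length / 2.0
    )
    nerve = nerve & sphere
    if not nerve.any():
        raise ValueError("nerve mask is empty at this resolution")

    rng = np.random.default_rng(spec.seed)

    # R2*: gel baseline, higher in tissue, bubbles scattered in the gel
    r2s = np.zeros(grid.shape)
    r2s[sphere] = spec.gel_r2star
    r2s[nerve] = spec.nerve_r2star
    gel_near = sphere & ~nerve
    candidates = np.flatnonzero(gel_near)
    if spec.n_bubbles > 0 and candidates.size:
        picks = rng.choice(candidates, size=min(spec.n_bubbles, candidates.size),
                           replace=False)
        r2s.flat[picks] = spec.bubble_r2star
    r2star = ScalarVolume(r2s, grid, "s^-1", sphere)

    inner_roi = erode(nerve, 1)
    mask_ppm = ScalarVolume(nerve.astype(float), grid, "ppm", sphere)
    nerve_axis = np.array([0.0, 0.0, 1.0])

    phantom = NervePhantom(spec, nerve, sphere)
    for k, angle in enumerate(spec.angles_deg):
        th = np.deg2rad(angle)
        h = np.array([np.sin(th), 0.0, np.cos(th)])
        ctx = FieldContext(tuple(h), spec.b0_strength)
        unit_iso = simulate_iso_field(mask_ppm, ctx)
        unit_aniso = cylsym_aniso_field(mask_ppm, nerve_axis, ctx)
        f_true = spec.chi_iso_true * unit_iso.data + spec.chi_aniso_true * unit_aniso.data
        resid = (spec.residual_amplitude * np.sin(th) ** 2 + spec.residual_offset)
        f_meas = f_true + resid * inner_roi
        meas_vol = ScalarVolume(f_meas, grid, "Hz", sphere)
        if spec.noise_sd > 0:
            meas_vol = add_noise(meas_vol, spec.noise_sd, spec.seed + 1000 + k)
        phantom.orientations.append(
            NervePhantomOrientation(
                angle_deg=float(angle),
                b0_direction=h,
                unit_iso=unit_iso.with_data(unit_iso.data, "Hz/ppm"),
                unit_aniso=unit_aniso.with_data(unit_aniso.data, "Hz/ppm"),
                f_true=ScalarVolume(f_true, grid, "Hz", sphere),
                f_meas=meas_vol,
                r2star=r2star,
            )
        )
    return phantom


# ---------------------------------------------------------------------------
# digitized brain model


@dataclass
class BrainSusceptibilityModel:
    """Geometric whole-brain susceptibility model.

    chi_iso carries the tissue isotropic susceptibility (WM at -0.05 ppm
    relative to non-WM tissue, deep grey structures at literature values);
    chi_aniso carries the cylindrically symmetric anisotropy magnitude
    (0.0113 ppm scaled by FA normalised to the optic-nerve value 0.59),
    nonzero only in WM; fiber_dirs are unit vectors inside WM and zero
    elsewhere.
    """

    grid: GridSpec
    chi_iso: ScalarVolume  # ppm
    chi_aniso: ScalarVolume  # ppm
    fiber_dirs: np.ndarray  # shape + (3,)
    fa: ScalarVolume  # dimensionless
    wm_mask: np.ndarray
    deep_gm_masks: dict[str, np.ndarray]
    brain_mask: np.ndarray
    tract_masks: dict[str, np.ndarray]

    @property
    def csf_gm_mask(self) -> np.ndarray:
        """Brain voxels with zero model susceptibility (CSF / cortical GM)."""
        deep = np.zeros(self.grid.shape, dtype=bool)
        for m in self.deep_gm_masks.values():
            deep |= m
        return self.brain_mask & ~self.wm_mask & ~deep


DEEP_GM_CHI = {"GP": 0.15, "PU": 0.05, "CN": 0.05, "TH": 0.00, "PV": 0.03}
WM_CHI_ISO = -0.05
WM_CHI_ANISO = 0.0113
FA_REFERENCE = 0.59


def _ellipsoid(x, y, z, center, semi) -> np.ndarray:
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def make_brain_model(
    grid: GridSpec = GridSpec((64, 64, 64), (3.0, 3.0, 3.0), pad_factor=2.0),
    seed: int = 0,
) -> BrainSusceptibilityModel:
    """Build the default geometric brain model.

    The brain is an ellipsoid; WM is an interior ellipsoid from which the
    deep-GM ellipsoids are carved.  Three analytic tract systems give the
    fiber field its large-scale structure: a left-right arch over the
    midline (corpus-callosum-like), paired inferior-superior columns
    (internal-capsule-like) and paired anterior-posterior bundles
    (optic-radiation-like); the remaining WM carries a smooth low-coherence
    background direction field.  FA is high on tract cores and decays into
    the background, with a small seeded smooth modulation.
    """
    x, y, z = grid.coords()
    shape = grid.shape

    brain = _ellipsoid(x, y, z, (0, 0, 0), (75, 90, 70))
    wm_region = _ellipsoid(x, y, z, (0, 0, 0), (55, 70, 50))

    deep_gm: dict[str, np.ndarray] = {}
    specs = {
        "GP": ((18, 5, 0), (6, 8, 6)),
        "PU": ((26, 8, 0), (6, 10, 7)),
        "CN": ((14, 28, 5), (5, 9, 6)),
        "TH": ((10, -8, 0), (8, 10, 7)),
        "PV": ((12, -20, 2), (4, 6, 4)),
    }
    for name, (center, semi) in specs.items():
        m = _ellipsoid(x, y, z, center, semi) | _ellipsoid(
            x, y, z, (-center[0], center[1], center[2]), semi
        )
        deep_gm[name] = m & brain
    deep_all = np.zeros(shape, dtype=bool)
    # PV overlaps TH; make the masks disjoint so region chi values are unambiguous
    order = ["PV", "GP", "PU", "CN", "TH"]
    for name in order:
        deep_gm[name] = deep_gm[name] & ~deep_all
        deep_all |= deep_gm[name]

    wm = wm_region & ~deep_all

    # --- tract systems -----------------------------------------------------
    bx = np.broadcast_to(x, shape)
    by = np.broadcast_to(y, shape)
    bz = np.broadcast_to(z, shape)

    # corpus-callosum-like arch: tangent field of a circle in the x-z plane
    arch_c = (0.0, 10.0)  # (x, z) centre, radius below
    arch_r = 25.0
    rad = np.sqrt((bx - arch_c[0]) ** 2 + (bz - arch_c[1]) ** 2)
    cc = (np.abs(rad - arch_r) <= 6.0) & (np.abs(by) <= 30.0) & (bz >= arch_c[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        tangent = np.stack(
            [(bz - arch_c[1]) / rad, np.zeros(shape), -(bx - arch_c[0]) / rad], axis=-1
        )
    tangent = np.nan_to_num(tangent)

    # internal-capsule-like columns: vertical, direction z
    ic = (((bx - 20) ** 2 + (by - 0) ** 2) <= 8.0**2) | (
        ((bx + 20) ** 2 + (by - 0) ** 2) <= 8.0**2
    )
    ic = ic & (np.abs(bz) <= 30.0)

    # optic-radiation-like bundles: anterior-posterior, direction y
    orad = (((bx - 30) ** 2 + (bz + 5) ** 2) <= 7.0**2) | (
        ((bx + 30) ** 2 + (bz + 5) ** 2) <= 7.0**2
    )
    orad = orad & (by >= -65.0) & (by <= 15.0)

    cc, ic, orad = cc & wm, ic & wm, orad & wm

    # background direction: smooth unit field bending from A-P towards L-R
    bg = np.stack(
        [
            np.sin(np.pi * by / 160.0),
            np.cos(np.pi * bx / 200.0),
            0.3 * np.sin(np.pi * bx / 120.0),
        ],
        axis=-1,
    )

    dirs = bg.copy()
    dirs[orad] = np.array([0.0, 1.0, 0.0])
    dirs[ic] = np.array([0.0, 0.0, 1.0])
    dirs[cc] = tangent[cc]
    norms = np.linalg.norm(dirs, axis=-1, keepdims=True)
    dirs = np.where(norms > 0, dirs / np.maximum(norms, 1e-12), 0.0)
    dirs[~wm] = 0.0

    # --- FA map ------------------------------------------------------------
    fa = np.zeros(shape)
    fa[wm] = 0.35
    for tract in (cc, ic, orad):
        fa[tract] = 0.85
    fa = ndimage.gaussian_filter(fa, sigma=1.0)
    rng = np.random.default_rng(seed)
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), sigma=2.0)
    texture /= max(texture.std(), 1e-12)
    fa += 0.03 * texture
    fa = np.clip(fa, 0.0, 1.0)
    fa[~wm] = 0.0

    # --- susceptibility maps ----------------------------------------------
    chi_iso = np.zeros(shape)
    chi_iso[wm] = WM_CHI_ISO
    for name, m in deep_gm.items():
        chi_iso[m] = DEEP_GM_CHI[name]

    chi_aniso = np.zeros(shape)
    chi_aniso[wm] = WM_CHI_ANISO * fa[wm] / FA_REFERENCE

    return BrainSusceptibilityModel(
        grid=grid,
        chi_iso=ScalarVolume(chi_iso, grid, "ppm", brain),
        chi_aniso=ScalarVolume(chi_aniso, grid, "ppm", brain),
        fiber_dirs=dirs,
        fa=ScalarVolume(fa, grid, "dimensionless", brain),
        wm_mask=wm,
        deep_gm_masks=deep_gm,
        brain_mask=brain,
        tract_masks={"cc": cc, "ic": ic, "or": orad},
    )
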