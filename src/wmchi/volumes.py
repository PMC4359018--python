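"""Core containers for 3D field data.

Everything in the pipeline moves as 3D scalar or tensor fields sampled on a
regular voxel grid: frequency maps in Hz, susceptibility maps in ppm, R2* maps
in 1/s, binary masks.  :class:`GridSpec` fixes the sampling (shape, voxel size
and the zero-padding factor used for Fourier-domain convolutions),
:class:`FieldContext` fixes the acquisition physics (B0 direction and strength,
echo times), and :class:`ScalarVolume` / :class:`SymmetricTensorVolume` carry
the data with a units tag.

Volumes are written to NIfTI-1 with a small JSON sidecar recording the units
and pad factor, so that round-tripping through disk is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

# gyromagnetic ratio of the proton, MHz/T (equivalently Hz per ppm per tesla)
GAMMA_BAR_MHZ_PER_T = 42.577

VALID_UNITS = {"Hz", "ppm", "s^-1", "dimensionless", "Hz/ppm"}


def larmor_scale(b0_strength: float) -> float:
    """Frequency-per-susceptibility scale in Hz per ppm at field ``b0_strength``.

    A susceptibility offset of ``x`` ppm produces local frequency shifts of
    order ``x * larmor_scale(B0)`` Hz; at 7 T this is about 298 Hz/ppm, so
    0.01 ppm corresponds to a shift of roughly 3 Hz.
    """
    if not b0_strength > 0:
        raise ValueError(f"B0 strength must be positive, got {b0_strength}")
    return GAMMA_BAR_MHZ_PER_T * b0_strength


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D sampling grid.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis; each entry must be at least 8.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    pad_factor : float
        Zero-padding factor applied before Fourier-domain convolutions, to
        suppress circular wrap-around.  ``1`` means no padding (the discrete
        model is then exactly circular, which is what the inversion modules
        assume); ``2`` is the default for physical forward simulation.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    pad_factor: float = 2.0

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        voxel = tuple(float(v) for v in self.voxel_size)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", voxel)
        if len(shape) != 3 or len(voxel) != 3:
            raise ValueError("GridSpec is strictly three dimensional")
        if any(n < 8 for n in shape):
            raise ValueError(f"all grid dimensions must be >= 8, got {shape}")
        if any(v <= 0 for v in voxel):
            raise ValueError(f"voxel sizes must be positive, got {voxel}")
        if self.pad_factor < 1:
            raise ValueError(f"pad_factor must be >= 1, got {self.pad_factor}")

    @property
    def padded_shape(self) -> tuple[int, int, int]:
        return tuple(int(np.ceil(n * self.pad_factor)) for n in self.shape)

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates in mm, origin at the grid centre."""
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * v
            for n, v in zip(self.shape, self.voxel_size)
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=True)

    def with_pad(self, pad_factor: float) -> "GridSpec":
        return replace(self, pad_factor=pad_factor)


@dataclass(frozen=True)
class FieldContext:
    """Acquisition physics: main field and echo timing.

    ``b0_direction`` is a unit vector in the laboratory frame.  Orientation
    changes are modelled by rotating this vector, never by resampling volumes.
    """

    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    b0_strength: float = 7.0
    te1: float = 0.007
    te2: float = 0.020

    def __post_init__(self):
        h = np.asarray(self.b0_direction, dtype=float)
        norm = np.linalg.norm(h)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"B0 direction must be a unit vector, |h| = {norm}")
        object.__setattr__(self, "b0_direction", tuple(h))
        if not self.b0_strength > 0:
            raise ValueError("B0 strength must be positive")
        if not self.te2 > self.te1:
            raise ValueError("TE2 must exceed TE1")

    @property
    def h(self) -> np.ndarray:
        return np.asarray(self.b0_direction, dtype=float)

    @property
    def larmor_scale(self) -> float:
        """Hz per ppm at this field strength."""
        return larmor_scale(self.b0_strength)

    @property
    def delta_te(self) -> float:
        return self.te2 - self.te1

    def with_direction(self, h) -> "FieldContext":
        h = np.asarray(h, dtype=float)
        h = h / np.linalg.norm(h)
        return replace(self, b0_direction=tuple(h))


@dataclass
class ScalarVolume:
    """One physical quantity sampled on a grid, with a units tag."""

    data: np.ndarray
    grid: GridSpec
    units: str
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected {VALID_UNITS}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape does not match data shape")
            if not np.all(np.isfinite(self.data[self.mask])):
                raise ValueError("non-finite values inside mask")

    def with_data(self, data: np.ndarray, units: str | None = None) -> "ScalarVolume":
        return ScalarVolume(data, self.grid, units or self.units, self.mask)

    def to_nifti(self, path) -> None:
        path = Path(path)
        affine = np.diag(list(self.grid.voxel_size) + [1.0])
        img = nib.Nifti1Image(self.data.astype(np.float64), affine)
        nib.save(img, str(path))
        sidecar = _sidecar_path(path)
        meta = {
            "units": self.units,
            "pad_factor": self.grid.pad_factor,
            "voxel_size": list(self.grid.voxel_size),
        }
        sidecar.write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_nifti(cls, path, mask: np.ndarray | None = None) -> "ScalarVolume":
        path = Path(path)
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        sidecar = _sidecar_path(path)
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        voxel = meta.get("voxel_size", [float(z) for z in img.header.get_zooms()[:3]])
        grid = GridSpec(data.shape, tuple(voxel), meta.get("pad_factor", 2.0))
        return cls(data, grid, meta.get("units", "dimensionless"), mask)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


# order of the unique components of a symmetric 3x3 tensor
TENSOR_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")
_IDX = {"xx": (0, 0), "yy": (1, 1), "zz": (2, 2),
        "xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


@dataclass
class SymmetricTensorVolume:
    """Six unique components of a symmetric susceptibility tensor per voxel.

    Component order is (xx, yy, zz, xy, xz, yz), stacked on the last axis of
    ``components`` (shape ``grid.shape + (6,)``), values in ppm.
    """

    components: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != self.grid.shape + (6,):
            raise ValueError(
                f"components shape {self.components.shape} != {self.grid.shape + (6,)}"
            )

    @classmethod
    def zeros(cls, grid: GridSpec) -> "SymmetricTensorVolume":
        return cls(np.zeros(grid.shape + (6,)), grid)

    @classmethod
    def isotropic(cls, chi: np.ndarray, grid: GridSpec) -> "SymmetricTensorVolume":
        comps = np.zeros(grid.shape + (6,))
        for i in range(3):
            comps[..., i] = chi
        return cls(comps, grid)

    @classmethod
    def from_matrix_field(cls, mats: np.ndarray, grid: GridSpec) -> "SymmetricTensorVolume":
        comps = np.stack([mats[(...,) + _IDX[c]] for c in TENSOR_COMPONENTS], axis=-1)
        return cls(comps, grid)

    def component(self, name: str) -> np.ndarray:
        return self.components[..., TENSOR_COMPONENTS.index(name)]

    def as_matrix_field(self) -> np.ndarray:
        """Full 3x3 symmetric matrices, shape ``grid.shape + (3, 3)``."""
        mats = np.zeros(self.grid.shape + (3, 3))
        for k, name in enumerate(TENSOR_COMPONENTS):
            i, j = _IDX[name]
            mats[..., i, j] = self.components[..., k]
            mats[..., j, i] = self.components[..., k]
        return mats

    def __add__(self, other: "SymmetricTensorVolume") -> "SymmetricTensorVolume":
        return SymmetricTensorVolume(self.components + other.components, self.grid)

    def scaled(self, factor: float) -> "SymmetricTensorVolume":
        return SymmetricTensorVolume(self.components * factor, self.grid)

    def trace(self) -> np.ndarray:
        return self.components[..., :3].sum(axis=-1)

    def traceless_part(self) -> "SymmetricTensorVolume":
        comps = self.components.copy()
        mean = self.trace() / 3.0
        for i in range(3):
            comps[..., i] -= mean
        return SymmetricTensorVolume(comps, self.grid)

    def to_nifti(self, path) -> None:
        path = Path(path)
        affine = np.diag(list(self.grid.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.components.astype(np.float64), affine), str(path))
        meta = {"units": "ppm", "components": list(TENSOR_COMPONENTS),
                "pad_factor": self.grid.pad_factor,
                "voxel_size": list(self.grid.voxel_size)}
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_nifti(cls, path) -> "SymmetricTensorVolume":
        path = Path(path)
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        sidecar = _sidecar_path(path)
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        voxel = meta.get("voxel_size", [float(z) for z in img.header.get_zooms()[:3]])
        grid = GridSpec(data.shape[:3], tuple(voxel), meta.get("pad_factor", 2.0))
        return cls(data, grid)


def cylsym_tensor(chi_iso: float, chi_aniso: float, axis) -> np.ndarray:
    """Cylindrically symmetric susceptibility tensor as a 3x3 matrix (ppm).

    Convention: ``X = chi_iso * I + chi_aniso * (3/2) (n n^T - I/3)``, so the
    principal-axis eigenvalue is ``chi_iso + chi_aniso`` and the two
    perpendicular eigenvalues are ``chi_iso - chi_aniso/2``.  The overall
    anisotropy is therefore ``chi_par - chi_perp = 1.5 * chi_aniso``.
    """
    n = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(n)
    if abs(norm - 1.0) > 1e-9:
        raise ValueError(f"principal axis must be a unit vector, |n| = {norm}")
    eye = np.eye(3)
    return chi_iso * eye + chi_aniso * 1.5 * (np.outer(n, n) - eye / 3.0)
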