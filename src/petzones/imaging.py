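"""Volume/mask data model, NIfTI I/O, SUV conversion and grid resampling.

The pipeline-wide convention is a fixed ``(x, y, z)`` index order with
0-based indices.  ``origin`` is the physical position (mm) of the centre of
voxel ``(0, 0, 0)``; voxel ``(i, j, k)`` sits at ``origin + index * spacing``.
Files are read and written as NIfTI-1 with a diagonal affine; any original
orientation information beyond spacing/translation is not interpreted.

SUV values are body-weight normalised and therefore dimensionless.  Inputs
are assumed decay-corrected to injection time; no decay correction is applied
here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Literal, Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateGridError,
    InvalidSpacingError,
    MissingFileError,
    NonVolumeDataError,
)

LesionClass = Literal["prostate_tumor", "lymph_node", "bone", "prostate_gland"]

__all__ = [
    "PETVolume",
    "ROIMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "suv_bodyweight",
    "resample_to_grid",
]


def _check_spacing(spacing: Tuple[float, float, float]) -> Tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in spacing):
        raise InvalidSpacingError(f"voxel spacing must be three positive numbers, got {spacing}")
    return spacing


@dataclass(frozen=True)
class PETVolume:
    """A 3D PET volume in SUV units on a regular anisotropic grid."""

    values: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise NonVolumeDataError(f"expected a 3D grid, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("SUV grid contains non-finite values")
        if arr.min() < 0:
            raise ValueError("SUV values must be non-negative")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class ROIMask:
    """Binary region of interest aligned to a :class:`PETVolume` grid."""

    values: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    lesion_class: LesionClass = "prostate_tumor"
    label: str = ""

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise NonVolumeDataError(f"expected a 3D mask, got shape {arr.shape}")
        object.__setattr__(self, "values", arr.astype(bool))
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def is_empty(self) -> bool:
        return not bool(self.values.any())

    def matches_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def _load_nifti(path: str):
    if not os.path.exists(path):
        raise MissingFileError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 else data
    if data.ndim != 3:
        raise NonVolumeDataError(f"{path}: expected 3D data, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise InvalidSpacingError(f"{path}: non-positive header spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, tuple(float(z) for z in zooms), origin


def read_volume(path: str) -> PETVolume:
    """Read a NIfTI SUV volume; spacing and origin come from the header."""
    data, spacing, origin = _load_nifti(path)
    return PETVolume(np.asarray(data, dtype=np.float64), spacing, origin)


def read_mask(path: str, lesion_class: LesionClass = "prostate_tumor", label: str = "") -> ROIMask:
    """Read a NIfTI binary mask (non-zero voxels are inside)."""
    data, spacing, origin = _load_nifti(path)
    return ROIMask(data > 0, spacing, origin, lesion_class=lesion_class, label=label)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: PETVolume, path: str) -> None:
    nib.save(nib.Nifti1Image(volume.values, _affine(volume.spacing, volume.origin)), path)


def write_mask(mask: ROIMask, path: str) -> None:
    nib.save(
        nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing, mask.origin)), path
    )


def suv_bodyweight(
    activity_concentration: np.ndarray,
    injected_dose_bq: float,
    body_weight_g: float,
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> PETVolume:
    """Body-weight SUV: ``concentration [Bq/mL] * weight [g] / dose [Bq]``.

    Inputs are assumed decay-corrected at injection; no decay term is applied.
    """
    if injected_dose_bq <= 0:
        raise ValueError(f"injected dose must be positive, got {injected_dose_bq}")
    if body_weight_g <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_g}")
    conc = np.asarray(activity_concentration, dtype=np.float64)
    return PETVolume(conc * (body_weight_g / injected_dose_bq), spacing, origin)


def _resample_grid(shape, spacing, target_spacing):
    target_spacing = _check_spacing(target_spacing)
    new_shape = tuple(
        int(round(n * s / t)) for n, s, t in zip(shape, spacing, target_spacing)
    )
    if min(new_shape) < 1:
        raise DegenerateGridError(
            f"target spacing {target_spacing} yields degenerate grid {new_shape}"
        )
    return new_shape, target_spacing


def _trilinear(values: np.ndarray, shape, spacing, origin, new_shape, new_spacing):
    # New grid keeps the outer physical edges aligned: the centre of new voxel
    # k sits at origin - s/2 + t*(k + 1/2) along each axis.
    coords = np.meshgrid(
        *[
            (np.arange(n) + 0.5) * t / s - 0.5
            for n, t, s in zip(new_shape, new_spacing, spacing)
        ],
        indexing="ij",
    )
    return ndimage.map_coordinates(values, coords, order=1, mode="nearest")


def resample_to_grid(obj, target_spacing, kind: Literal["image", "mask"] = "image"):
    """Resample a volume or mask to a new isotropic/anisotropic spacing.

    Images are interpolated trilinearly.  Masks interpolate the 0/1 indicator
    trilinearly and re-threshold at 0.5.  The physical extent of the grid is
    preserved to within one voxel.
    """
    new_shape, tsp = _resample_grid(obj.shape, obj.spacing, target_spacing)
    new_origin = tuple(
        o - s / 2.0 + t / 2.0 for o, s, t in zip(obj.origin, obj.spacing, tsp)
    )
    if kind == "mask":
        interp = _trilinear(
            obj.values.astype(np.float64), obj.shape, obj.spacing, obj.origin, new_shape, tsp
        )
        return replace(obj, values=interp >= 0.5, spacing=tsp, origin=new_origin)
    interp = _trilinear(obj.values, obj.shape, obj.spacing, obj.origin, new_shape, tsp)
    return replace(obj, values=np.clip(interp, 0.0, None), spacing=tsp, origin=new_origin)
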