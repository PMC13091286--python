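"""Volumetric data model for dose grids and structure masks.

Axis-aligned voxel grids only.  Arrays are indexed ``(i, j, k)`` with one
spacing entry per array axis (mm); the origin is the world position (mm) of
the centre of voxel ``(0, 0, 0)``.  A mask voxel belongs to a structure iff
its centre is inside the structure, so every metric downstream is
voxel-centre based.  Resampling between mismatched grids is deliberately out
of scope: cross-volume operations demand aligned geometry and raise
otherwise.

Files are read and written through SimpleITK, so both NIfTI
(``.nii``/``.nii.gz``) and MetaImage (``.mha``/``.mhd``) work.  SimpleITK
yields arrays with axes reversed relative to its world axes; spacing and
origin are reversed on the way in and out so they always line up with the
array axes held here, making round-trips exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "DoseGrid",
    "StructMask",
    "GeometryError",
    "read_volume",
    "write_volume",
    "check_aligned",
    "mask_volume",
]

#: tolerance (mm) for geometry comparisons
GEOM_ATOL_MM = 1e-6


class GeometryError(ValueError):
    """Raised when two volumes that must share a grid do not."""


def _validate_geometry(values: np.ndarray, spacing, origin) -> tuple[tuple, tuple]:
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if values.ndim != 3:
        raise ValueError(f"expected a 3-D array, got ndim={values.ndim}")
    if len(spacing) != 3 or len(origin) != 3:
        raise ValueError("spacing and origin must have three components")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    return spacing, origin


@dataclass(frozen=True)
class DoseGrid:
    """Absorbed dose per voxel (Gy) on an axis-aligned grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        spacing, origin = _validate_geometry(self.values, self.spacing, self.origin)
        values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(values)):
            raise ValueError("dose values must all be finite")
        n_neg = int(np.count_nonzero(values < 0))
        if n_neg:
            raise ValueError(f"dose grid contains {n_neg} negative voxel(s)")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class StructMask:
    """Boolean region-of-interest on the same grid convention as DoseGrid."""

    name: str
    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    allow_empty: bool = field(default=False, compare=False)

    def __post_init__(self):
        spacing, origin = _validate_geometry(self.values, self.spacing, self.origin)
        values = np.asarray(self.values) != 0
        if not values.any() and not self.allow_empty:
            raise ValueError(
                f"mask '{self.name}' has no member voxels; pass allow_empty=True "
                "if an empty structure is intended"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_empty(self) -> bool:
        return not bool(self.values.any())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.values))


def check_aligned(a, b, atol_mm: float = GEOM_ATOL_MM) -> bool:
    """True iff shape, spacing and origin agree within ``atol_mm``.

    Pure predicate used as the gate by every cross-volume operation.
    """
    if a.shape != b.shape:
        return False
    return bool(
        np.allclose(a.spacing, b.spacing, rtol=0.0, atol=atol_mm)
        and np.allclose(a.origin, b.origin, rtol=0.0, atol=atol_mm)
    )


def require_aligned(a, b) -> None:
    if not check_aligned(a, b):
        raise GeometryError(
            "volumes are not on the same grid: "
            f"shapes {a.shape} vs {b.shape}, spacings {a.spacing} vs {b.spacing}, "
            f"origins {a.origin} vs {b.origin}"
        )


def mask_volume(m: StructMask) -> float:
    """Structure volume in cm^3 (member-voxel count times voxel volume)."""
    if m.is_empty:
        warnings.warn(f"mask '{m.name}' is empty; volume 0", stacklevel=2)
        return 0.0
    return m.n_voxels * m.voxel_volume_mm3 / 1000.0


def read_volume(path, kind: str = "dose", name: str | None = None):
    """Read a NIfTI or MetaImage volume as a DoseGrid or StructMask.

    ``kind='mask'`` treats exactly the nonzero voxels as members; a file of
    zeros yields an empty-flagged mask.  ``kind='dose'`` validates finite,
    non-negative doses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # pragma: no cover - SimpleITK error text varies
        raise IOError(f"could not read volume {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim == 4 and arr.shape[0] == 1:
        arr = arr[0]
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    if kind == "dose":
        return DoseGrid(values=arr, spacing=spacing, origin=origin)
    if kind == "mask":
        return StructMask(
            name=name or path.name.split(".")[0],
            values=arr,
            spacing=spacing,
            origin=origin,
            allow_empty=True,
        )
    raise ValueError(f"kind must be 'dose' or 'mask', got {kind!r}")


def write_volume(vol, path) -> None:
    """Write a DoseGrid (float64) or StructMask (uint8 0/1) volume."""
    path = Path(path)
    if isinstance(vol, StructMask):
        arr = vol.values.astype(np.uint8)
    else:
        arr = np.asarray(vol.values, dtype=np.float64)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(reversed(vol.spacing)))
    img.SetOrigin(tuple(reversed(vol.origin)))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
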