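"""PET volume container, NIfTI I/O and SUV conversion.

A :class:`PetVolume` bundles a 3D voxel grid with its geometry and the
acquisition metadata needed for standardized-uptake-value (SUV) conversion.
Volumes and label masks are read and written as NIfTI rasters via nibabel;
the affine carries the voxel spacing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Units",
    "PetVolume",
    "suv_convert",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]


class Units(str, enum.Enum):
    """Voxel value units: raw activity concentration or SUV."""

    BQML = "BQML"
    SUV = "SUV"


@dataclass
class PetVolume:
    """3D PET raster with voxel geometry and acquisition metadata.

    Parameters
    ----------
    data:
        3D array of voxel values, either activity concentration in Bq/ml
        (``units=Units.BQML``) or unitless SUV (``units=Units.SUV``).
    voxel_size_mm:
        Physical voxel spacing along each axis, in mm.
    units:
        Unit flag for ``data``.
    patient_weight_kg, injected_activity_bq:
        Needed only for SUV conversion; the injected activity is assumed
        decay-corrected to scan time.
    batch_label:
        Scanner / reconstruction batch identifier.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    units: Units = Units.SUV
    patient_weight_kg: float | None = None
    injected_activity_bq: float | None = None
    batch_label: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_mm must be 3 positive values, got {self.voxel_size_mm}")
        self.voxel_size_mm = vs
        self.units = Units(self.units)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0


def suv_convert(volume: PetVolume) -> PetVolume:
    """Convert an activity-concentration volume (Bq/ml) to SUV.

    SUV = concentration [Bq/ml] x body weight [g] / injected activity [Bq],
    under the body-weight convention with tissue density 1 g/ml.  The
    injected activity must already be decay-corrected.

    Raises
    ------
    ValueError
        If the volume is already in SUV (no silent double conversion) or
        weight / injected activity are missing or non-positive.
    """
    if volume.units == Units.SUV:
        raise ValueError("volume is already in SUV units; refusing to convert twice")
    if volume.patient_weight_kg is None or volume.injected_activity_bq is None:
        raise ValueError("SUV conversion requires patient_weight_kg and injected_activity_bq")
    if volume.patient_weight_kg <= 0 or volume.injected_activity_bq <= 0:
        raise ValueError("patient weight and injected activity must be positive")
    weight_g = volume.patient_weight_kg * 1000.0
    suv = volume.data * weight_g / volume.injected_activity_bq
    return replace(volume, data=suv, units=Units.SUV)


def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def write_volume(volume: PetVolume, path: str | Path) -> None:
    """Write a volume to NIfTI (float32 data, spacing in the affine)."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.voxel_size_mm))
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))


def read_volume(path: str | Path, units: Units = Units.SUV, **metadata) -> PetVolume:
    """Read a 3D NIfTI volume.

    Voxel spacing is taken from the header zooms.  Extra keyword arguments
    (``patient_weight_kg``, ``batch_label``, ...) are forwarded to the
    :class:`PetVolume` constructor.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"missing or invalid voxel spacing in {path}: {zooms}")
    return PetVolume(
        data=np.asarray(data, dtype=np.float64),
        voxel_size_mm=tuple(float(z) for z in zooms),
        units=units,
        **metadata,
    )


def write_mask(mask: np.ndarray, voxel_size_mm: tuple[float, float, float], path: str | Path) -> None:
    """Write an integer label mask aligned with a volume grid as NIfTI."""
    arr = np.asarray(mask)
    if arr.ndim != 3:
        raise ValueError("mask must be 3D")
    img = nib.Nifti1Image(arr.astype(np.int16), _affine(tuple(float(v) for v in voxel_size_mm)))
    img.header.set_zooms(tuple(float(v) for v in voxel_size_mm))
    nib.save(img, str(path))


def read_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read an integer label mask; returns (labels, voxel_size_mm)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D mask, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    return np.asarray(data, dtype=np.int32), tuple(float(z) for z in zooms)
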