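"""Seeded lesion segmentation at a fraction of SUVmax, and per-lesion metrics.

Segmentation is the two-pass seeded scheme: a provisional 26-connected
region grown from the seed at ``fraction x SUV(seed)`` fixes the lesion
SUVmax, and the final mask is the 26-connected component of
``>= fraction x SUVmax`` voxels containing the seed (default fraction 0.4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import PetVolume, Units

__all__ = [
    "LesionMask",
    "LesionMetrics",
    "segment_lesion",
    "lesion_metrics",
    "total_mtv",
    "select_hottest",
    "suv_peak",
    "CONNECTIVITY_STRUCTURE",
]

# 26-neighbour connectivity in 3D
CONNECTIVITY_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class LesionMask:
    """Boolean lesion mask aligned with its source volume."""

    mask: np.ndarray
    lesion_id: int
    seed_voxel: tuple[int, int, int]

    def __post_init__(self):
        if self.mask.dtype != bool:
            object.__setattr__(self, "mask", self.mask.astype(bool))
        if not self.mask[self.seed_voxel]:
            raise ValueError("lesion mask does not contain its seed voxel")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class LesionMetrics:
    """Per-lesion volume and SUV statistics."""

    mtv_cm3: float
    suv_max: float
    suv_mean: float
    suv_min: float
    suv_peak: float
    tlg: float
    voxel_count: int


def _seed_component(above: np.ndarray, seed: tuple[int, int, int]) -> np.ndarray:
    labels, _ = ndimage.label(above, structure=CONNECTIVITY_STRUCTURE)
    lab = labels[seed]
    if lab == 0:
        raise ValueError("seed outside lesion: seed voxel below threshold")
    return labels == lab


def segment_lesion(
    volume: PetVolume,
    seed_voxel: tuple[int, int, int],
    threshold_fraction: float = 0.4,
    lesion_id: int = 1,
) -> LesionMask:
    """Segment one lesion by two-pass seeded region growing.

    Pass 1 grows a provisional 26-connected region of voxels with
    ``SUV >= threshold_fraction * SUV(seed)`` and takes its SUVmax; pass 2
    returns the 26-connected component containing the seed among voxels with
    ``SUV >= threshold_fraction * SUVmax``.  Threshold comparisons are ``>=``.
    """
    if volume.units != Units.SUV:
        raise ValueError("segmentation requires a volume in SUV units")
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError(f"threshold_fraction must be in (0, 1), got {threshold_fraction}")
    seed = tuple(int(i) for i in seed_voxel)
    if len(seed) != 3 or any(i < 0 or i >= s for i, s in zip(seed, volume.shape)):
        raise ValueError(f"seed voxel {seed} outside grid {volume.shape}")
    data = volume.data

    provisional = _seed_component(data >= threshold_fraction * data[seed], seed)
    suv_max = float(data[provisional].max())
    final = _seed_component(data >= threshold_fraction * suv_max, seed)
    return LesionMask(mask=final, lesion_id=lesion_id, seed_voxel=seed)


def suv_peak(volume: PetVolume, mask: np.ndarray, sphere_volume_mm3: float = 1000.0) -> float:
    """SUVpeak: the maximal sphere-mean over sphere centres inside the mask.

    The sphere (default 1 cm^3) is voxelized on the grid; sphere voxels
    falling outside the grid are excluded from the mean.
    """
    radius_mm = (3.0 * sphere_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    vs = volume.voxel_size_mm
    half = [int(np.floor(radius_mm / v)) for v in vs]
    grids = np.meshgrid(*[np.arange(-h, h + 1) * v for h, v in zip(half, vs)], indexing="ij")
    kernel = (grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2) <= radius_mm**2
    kernel = kernel.astype(np.float64)
    sums = ndimage.convolve(volume.data, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones_like(volume.data), kernel, mode="constant", cval=0.0)
    means = sums / counts
    return float(means[mask].max())


def lesion_metrics(volume: PetVolume, mask: np.ndarray | LesionMask) -> LesionMetrics:
    """Volume (MTV in cm^3), SUV statistics, SUVpeak and TLG over a mask."""
    arr = mask.mask if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)
    if arr.shape != volume.shape:
        raise ValueError(f"mask shape {arr.shape} does not match volume {volume.shape}")
    n = int(arr.sum())
    if n == 0:
        raise ValueError("empty lesion mask")
    vals = volume.data[arr]
    mtv = n * volume.voxel_volume_cm3
    mean = float(vals.mean())
    return LesionMetrics(
        mtv_cm3=mtv,
        suv_max=float(vals.max()),
        suv_mean=mean,
        suv_min=float(vals.min()),
        suv_peak=suv_peak(volume, arr),
        tlg=mtv * mean,
        voxel_count=n,
    )


def total_mtv(metrics: list[LesionMetrics]) -> float:
    """Total metabolic tumour volume: sum of per-lesion MTVs (cm^3)."""
    if not metrics:
        raise ValueError("no measurable lesions: total MTV undefined (patient excluded)")
    return float(sum(m.mtv_cm3 for m in metrics))


def select_hottest(metrics: list[LesionMetrics]) -> int:
    """Index of the lesion with the highest SUVmax.

    Ties are broken toward the larger MTV, then the lowest index.
    """
    if not metrics:
        raise ValueError("no lesions to select from")
    best = 0
    for i, m in enumerate(metrics[1:], start=1):
        b = metrics[best]
        if (m.suv_max, m.mtv_cm3) > (b.suv_max, b.mtv_cm3):
            best = i
    return best
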