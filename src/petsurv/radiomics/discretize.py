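"""Fixed-range grey-level discretization of a VOI.

SUVs are binned into 64 levels over the absolute range 0-32 SUV
(bin width 0.5 SUV): ``level = floor(SUV / 0.5) + 1`` clamped to [1, 64].
Values at or above 31.5 SUV therefore map to level 64; negative values
clamp to level 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..volume import PetVolume, Units

__all__ = ["DiscretizedVoi", "discretize", "BIN_WIDTH_SUV", "LEVEL_COUNT"]

BIN_WIDTH_SUV = 0.5
LEVEL_COUNT = 64


@dataclass(frozen=True)
class DiscretizedVoi:
    """Integer grey-level grid over a mask; 0 marks out-of-mask voxels."""

    levels: np.ndarray  # int array, 0 outside mask, 1..64 inside
    mask: np.ndarray  # bool
    n_voxels: int
    bin_width_suv: float = BIN_WIDTH_SUV
    level_count: int = LEVEL_COUNT

    def in_mask_levels(self) -> np.ndarray:
        """Flat array of in-mask grey levels."""
        return self.levels[self.mask]


def discretize(volume: PetVolume, mask: np.ndarray) -> DiscretizedVoi:
    """Discretize the masked SUVs of ``volume`` into 64 levels over 0-32 SUV."""
    if volume.units != Units.SUV:
        raise ValueError("discretization requires a volume in SUV units")
    m = np.asarray(mask, dtype=bool)
    if m.shape != volume.shape:
        raise ValueError("mask shape does not match volume")
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty mask")
    lv = np.floor(volume.data / BIN_WIDTH_SUV).astype(np.int64) + 1
    np.clip(lv, 1, LEVEL_COUNT, out=lv)
    lv[~m] = 0
    return DiscretizedVoi(levels=lv, mask=m, n_voxels=n)
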