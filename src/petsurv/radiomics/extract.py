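"""Full 41-feature extraction from one lesion VOI."""

from __future__ import annotations

import numpy as np

from ..segmentation import lesion_metrics
from ..volume import PetVolume
from .discretize import discretize
from .glcm import glcm_features
from .glrlm import glrlm_features
from .glszm import glszm_features
from .histogram import histogram_features
from .ngldm import ngldm_features
from .registry import ALL_FEATURES

__all__ = ["extract_features", "MIN_VOXELS", "LesionTooSmallError"]

#: Minimum VOI size for a meaningful texture analysis.
MIN_VOXELS = 64


class LesionTooSmallError(ValueError):
    """Raised when a lesion is below the texture-analysis voxel minimum."""


def extract_features(
    volume: PetVolume,
    mask: np.ndarray,
    min_voxels: int = MIN_VOXELS,
) -> dict[str, float]:
    """Extract the 41 conventional + histogram + texture features.

    Returns an ordered dict keyed by the canonical registry names.  Lesions
    smaller than ``min_voxels`` voxels are rejected (texture statistics are
    unreliable below that size).
    """
    arr = np.asarray(mask, dtype=bool)
    n = int(arr.sum())
    if n < min_voxels:
        raise LesionTooSmallError(
            f"lesion has {n} voxels, below the {min_voxels}-voxel minimum for radiomic analysis"
        )
    conv = lesion_metrics(volume, arr)
    voi = discretize(volume, arr)

    values: dict[str, float] = {
        "CONV_SUVmax": conv.suv_max,
        "CONV_SUVmean": conv.suv_mean,
        "CONV_SUVmin": conv.suv_min,
        "CONV_SUVpeak": conv.suv_peak,
        "CONV_TLG": conv.tlg,
    }
    values.update(histogram_features(voi))
    values.update(glcm_features(voi))
    values.update(glrlm_features(voi))
    values.update(ngldm_features(voi))
    values.update(glszm_features(voi))

    ordered = {name: float(values[name]) for name in ALL_FEATURES}
    if len(ordered) != 41:  # pragma: no cover - registry guards this
        raise RuntimeError("feature registry mismatch")
    return ordered
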