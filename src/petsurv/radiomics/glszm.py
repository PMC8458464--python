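"""Grey-level size-zone matrix (GLSZM / GLZLM) features.

A zone is a maximal 26-connected component of in-mask voxels sharing one
grey level.  The matrix counts zones by (level, size); long/large-zone
emphasis (LZE) weights zones by squared size.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedVoi

__all__ = ["glszm_matrix", "glszm_features"]

_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(voi: DiscretizedVoi) -> np.ndarray:
    """Zone count matrix, shape (levels, max_zone_size)."""
    max_size = voi.n_voxels
    m = np.zeros((voi.level_count, max_size), dtype=np.float64)
    present = np.unique(voi.in_mask_levels())
    for g in present:
        labels, n_zones = ndimage.label(voi.levels == g, structure=_STRUCTURE)
        if n_zones == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        for s in sizes:
            m[g - 1, s - 1] += 1.0
    return m


def glszm_features(voi: DiscretizedVoi) -> dict[str, float]:
    """The eleven GLZLM features; zone percentage is zones per voxel."""
    m = glszm_matrix(voi)
    nz = m.sum()
    if nz == 0:
        raise ValueError("empty VOI: GLZLM undefined")
    g = np.arange(1, m.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, m.shape[1] + 1, dtype=np.float64)[None, :]
    return {
        "GLZLM_SZE": float((m / s**2).sum() / nz),
        "GLZLM_LZE": float((m * s**2).sum() / nz),
        "GLZLM_LGZE": float((m / g**2).sum() / nz),
        "GLZLM_HGZE": float((m * g**2).sum() / nz),
        "GLZLM_SZLGE": float((m / (g**2 * s**2)).sum() / nz),
        "GLZLM_SZHGE": float((m * g**2 / s**2).sum() / nz),
        "GLZLM_LZLGE": float((m * s**2 / g**2).sum() / nz),
        "GLZLM_LZHGE": float((m * g**2 * s**2).sum() / nz),
        "GLZLM_GLNU": float((m.sum(axis=1) ** 2).sum() / nz),
        "GLZLM_ZLNU": float((m.sum(axis=0) ** 2).sum() / nz),
        "GLZLM_ZP": float(nz / voi.n_voxels),
    }
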