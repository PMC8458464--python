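"""Grey-level co-occurrence matrix (GLCM) features.

Co-occurrences are accumulated at distance 1 over the 13 unique 3D
directions, restricted to in-mask voxel pairs, symmetrized and pooled into a
single matrix before normalization.  Entropy uses log base 2.
"""

from __future__ import annotations

import numpy as np

from ._directions import DIRECTIONS_13
from .discretize import DiscretizedVoi

__all__ = ["glcm_matrix", "glcm_features"]


def _shifted_pairs(levels: np.ndarray, mask: np.ndarray, d: tuple[int, int, int]):
    """In-mask (level, level) pairs one step apart along direction ``d``."""
    sl_a, sl_b = [], []
    for ax, step in enumerate(d):
        n = levels.shape[ax]
        if step == 1:
            sl_a.append(slice(0, n - 1))
            sl_b.append(slice(1, n))
        elif step == -1:
            sl_a.append(slice(1, n))
            sl_b.append(slice(0, n - 1))
        else:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
    a = levels[tuple(sl_a)]
    b = levels[tuple(sl_b)]
    valid = mask[tuple(sl_a)] & mask[tuple(sl_b)]
    return a[valid], b[valid]


def glcm_matrix(voi: DiscretizedVoi) -> np.ndarray:
    """Pooled symmetric co-occurrence count matrix, shape (levels, levels)."""
    g = voi.level_count
    counts = np.zeros((g, g), dtype=np.float64)
    for d in DIRECTIONS_13:
        a, b = _shifted_pairs(voi.levels, voi.mask, d)
        if a.size:
            np.add.at(counts, (a - 1, b - 1), 1.0)
    return counts + counts.T  # symmetrize


def glcm_features(voi: DiscretizedVoi) -> dict[str, float]:
    """The six GLCM features from the pooled normalized matrix."""
    counts = glcm_matrix(voi)
    total = counts.sum()
    if total == 0:
        raise ValueError("no adjacent in-mask voxel pairs: GLCM undefined")
    p = counts / total
    g = voi.level_count
    i = np.arange(1, g + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj)

    px = p.sum(axis=1)  # symmetric: px == py
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())
    if var > 0:
        correlation = float((((ii - mu) * (jj - mu)) * p).sum() / var)
    else:
        correlation = 0.0  # degenerate single-level fallback

    nz = p[p > 0]
    return {
        "GLCM_Homogeneity": float((p / (1.0 + diff)).sum()),
        "GLCM_Energy": float((p**2).sum()),
        "GLCM_Contrast": float((p * diff**2).sum()),
        "GLCM_Correlation": correlation,
        "GLCM_Entropy": float(-(nz * np.log2(nz)).sum()),
        "GLCM_Dissimilarity": float((p * diff).sum()),
    }
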