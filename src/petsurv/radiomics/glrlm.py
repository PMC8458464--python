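"""Grey-level run-length matrix (GLRLM) features.

Runs are maximal in-mask segments of constant grey level along one of the 13
unique 3D directions.  Per-direction matrices are summed into a single matrix
before normalization; the run percentage divides by ``n_voxels x 13``.
A per-direction matrix hook (:func:`glrlm_matrix`) is exposed for testing
against direction-specific worked examples.
"""

from __future__ import annotations

import numpy as np

from ._directions import DIRECTIONS_13
from .discretize import DiscretizedVoi

__all__ = ["glrlm_matrix", "glrlm_matrix_pooled", "glrlm_features"]


def _in_grid(idx: tuple[int, int, int], shape: tuple[int, ...]) -> bool:
    return all(0 <= i < s for i, s in zip(idx, shape))


def glrlm_matrix(voi: DiscretizedVoi, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length count matrix for one direction, shape (levels, max_run)."""
    levels = voi.levels
    mask = voi.mask
    shape = levels.shape
    longest = max(shape)  # a run cannot exceed the longest axis extent
    m = np.zeros((voi.level_count, longest), dtype=np.float64)
    d = tuple(int(x) for x in direction)
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        prev = tuple(i - s for i, s in zip(idx, d))
        # run starts where the predecessor is absent or differs in level
        if _in_grid(prev, shape) and mask[prev] and levels[prev] == levels[idx]:
            continue
        g = levels[idx]
        length = 1
        nxt = tuple(i + s for i, s in zip(idx, d))
        while _in_grid(nxt, shape) and mask[nxt] and levels[nxt] == g:
            length += 1
            nxt = tuple(i + s for i, s in zip(nxt, d))
        if length > m.shape[1]:
            m = np.pad(m, ((0, 0), (0, length - m.shape[1])))
        m[g - 1, length - 1] += 1.0
    return m


def glrlm_matrix_pooled(voi: DiscretizedVoi) -> np.ndarray:
    """Sum of the 13 per-direction run-length matrices."""
    mats = [glrlm_matrix(voi, d) for d in DIRECTIONS_13]
    width = max(m.shape[1] for m in mats)
    pooled = np.zeros((voi.level_count, width), dtype=np.float64)
    for m in mats:
        pooled[:, : m.shape[1]] += m
    return pooled


def glrlm_features(voi: DiscretizedVoi) -> dict[str, float]:
    """The eleven GLRLM features from the direction-pooled matrix."""
    m = glrlm_matrix_pooled(voi)
    n_runs = m.sum()
    if n_runs == 0:
        raise ValueError("empty VOI: GLRLM undefined")
    g = np.arange(1, m.shape[0] + 1, dtype=np.float64)[:, None]
    r = np.arange(1, m.shape[1] + 1, dtype=np.float64)[None, :]
    return {
        "GLRLM_SRE": float((m / r**2).sum() / n_runs),
        "GLRLM_LRE": float((m * r**2).sum() / n_runs),
        "GLRLM_LGRE": float((m / g**2).sum() / n_runs),
        "GLRLM_HGRE": float((m * g**2).sum() / n_runs),
        "GLRLM_SRLGE": float((m / (g**2 * r**2)).sum() / n_runs),
        "GLRLM_SRHGE": float((m * g**2 / r**2).sum() / n_runs),
        "GLRLM_LRLGE": float((m * r**2 / g**2).sum() / n_runs),
        "GLRLM_LRHGE": float((m * g**2 * r**2).sum() / n_runs),
        "GLRLM_GLNU": float((m.sum(axis=1) ** 2).sum() / n_runs),
        "GLRLM_RLNU": float((m.sum(axis=0) ** 2).sum() / n_runs),
        "GLRLM_RP": float(n_runs / (voi.n_voxels * len(DIRECTIONS_13))),
    }
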