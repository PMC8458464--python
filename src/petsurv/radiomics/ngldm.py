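"""Neighbourhood grey-level difference (NGLDM) features.

For each in-mask voxel the absolute difference between its grey level and
the mean level of its in-mask 26-neighbours is accumulated per level
(out-of-mask neighbours are excluded from the mean; voxels with no in-mask
neighbour are skipped).  Coarseness, contrast and busyness follow the
classic neighbourhood-difference definitions.

Degenerate guards: a perfectly homogeneous VOI has zero total difference;
coarseness is then capped at 1e6 (documented convention) and contrast and
busyness are 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedVoi

__all__ = ["ngldm_components", "ngldm_features"]

_COARSENESS_CAP = 1.0e6
_NEIGHBOUR_KERNEL = np.ones((3, 3, 3), dtype=np.float64)
_NEIGHBOUR_KERNEL[1, 1, 1] = 0.0


def ngldm_components(voi: DiscretizedVoi):
    """Per-level occurrence probabilities p_g and difference sums s_g.

    Returns ``(levels, p, s, n_valid)`` where ``levels`` are the grey levels
    with at least one counted voxel, ``p`` their occurrence fractions among
    counted voxels, ``s`` the summed absolute differences to the neighbour
    mean, and ``n_valid`` the number of counted voxels.
    """
    lv = voi.levels.astype(np.float64)
    mask = voi.mask
    nb_sum = ndimage.convolve(np.where(mask, lv, 0.0), _NEIGHBOUR_KERNEL, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(mask.astype(np.float64), _NEIGHBOUR_KERNEL, mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no voxel with an in-mask neighbour: NGLDM undefined")
    g_vals = voi.levels[valid]
    diffs = np.abs(g_vals - nb_sum[valid] / nb_cnt[valid])

    levels = np.unique(g_vals)
    p = np.array([(g_vals == g).sum() for g in levels], dtype=np.float64) / n_valid
    s = np.array([diffs[g_vals == g].sum() for g in levels], dtype=np.float64)
    return levels.astype(np.float64), p, s, n_valid


def ngldm_features(voi: DiscretizedVoi) -> dict[str, float]:
    levels, p, s, n_valid = ngldm_components(voi)
    ps = float((p * s).sum())

    coarseness = 1.0 / ps if ps > 0 else _COARSENESS_CAP
    coarseness = min(coarseness, _COARSENESS_CAP)

    n_g = len(levels)
    if n_g > 1:
        gi = levels[:, None]
        gj = levels[None, :]
        pij = p[:, None] * p[None, :]
        contrast = float((pij * (gi - gj) ** 2).sum()) / (n_g * (n_g - 1)) * (s.sum() / n_valid)
        denom = float(np.abs(gi * p[:, None] - gj * p[None, :]).sum())
        busyness = ps / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0

    return {
        "NGLDM_Coarseness": float(coarseness),
        "NGLDM_Contrast": float(contrast),
        "NGLDM_Busyness": float(busyness),
    }
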