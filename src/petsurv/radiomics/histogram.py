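"""Intensity-histogram descriptors on the 64-level discretized VOI.

Skewness and kurtosis use the Fisher convention (kurtosis is excess);
degenerate single-level VOIs return 0 for both (0/0 guard).  Entropy is
reported in both log2 and log10; zero-probability bins are skipped.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedVoi

__all__ = ["histogram_features"]


def histogram_features(voi: DiscretizedVoi) -> dict[str, float]:
    g = voi.in_mask_levels().astype(np.float64)
    if g.size == 0:
        raise ValueError("empty VOI: histogram undefined")
    counts = np.bincount(voi.in_mask_levels(), minlength=voi.level_count + 1)[1:]
    p = counts / counts.sum()

    mu = g.mean()
    m2 = ((g - mu) ** 2).mean()
    if m2 > 0:
        m3 = ((g - mu) ** 3).mean()
        m4 = ((g - mu) ** 4).mean()
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    else:
        skew = 0.0
        kurt = 0.0

    nz = p[p > 0]
    return {
        "HISTO_Skewness": float(skew),
        "HISTO_Kurtosis": float(kurt),
        "HISTO_EntropyLog2": float(-(nz * np.log2(nz)).sum()),
        "HISTO_EntropyLog10": float(-(nz * np.log10(nz)).sum()),
        "HISTO_Energy": float((p**2).sum()),
    }
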