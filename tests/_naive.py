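"""Independent brute-force reference implementations for texture features.

These are deliberately slow, loop-based and structured differently from the
package code (line-scan run-length encoding, BFS flood fill, explicit
neighbour loops) so they can serve as oracles.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict, deque

import numpy as np

OFFSETS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
DIRECTIONS_13 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]


def _in_grid(p, shape):
    return all(0 <= a < s for a, s in zip(p, shape))


# --- GLCM ------------------------------------------------------------------


def naive_glcm_counts(levels, mask):
    counts = defaultdict(float)
    shape = levels.shape
    for p in itertools.product(*[range(s) for s in shape]):
        if not mask[p]:
            continue
        for off in OFFSETS_26:
            q = tuple(a + o for a, o in zip(p, off))
            if _in_grid(q, shape) and mask[q]:
                counts[(int(levels[p]), int(levels[q]))] += 1.0
    return counts


def naive_glcm_features(levels, mask):
    counts = naive_glcm_counts(levels, mask)
    total = sum(counts.values())
    assert total > 0
    p = {k: v / total for k, v in counts.items()}

    homog = sum(v / (1 + abs(i - j)) for (i, j), v in p.items())
    energy = sum(v * v for v in p.values())
    contrast = sum(v * (i - j) ** 2 for (i, j), v in p.items())
    dissim = sum(v * abs(i - j) for (i, j), v in p.items())
    entropy = -sum(v * math.log2(v) for v in p.values() if v > 0)
    mu = sum(v * i for (i, _), v in p.items())
    var = sum(v * (i - mu) ** 2 for (i, _), v in p.items())
    if var > 0:
        corr = sum(v * (i - mu) * (j - mu) for (i, j), v in p.items()) / var
    else:
        corr = 0.0
    return {
        "GLCM_Homogeneity": homog,
        "GLCM_Energy": energy,
        "GLCM_Contrast": contrast,
        "GLCM_Correlation": corr,
        "GLCM_Entropy": entropy,
        "GLCM_Dissimilarity": dissim,
    }


# --- GLRLM -----------------------------------------------------------------


def naive_runs(levels, mask, direction):
    """All maximal constant-level in-mask runs along one direction,
    found by run-length-encoding whole grid lines."""
    shape = levels.shape
    runs = []
    for start in itertools.product(*[range(s) for s in shape]):
        prev = tuple(a - o for a, o in zip(start, direction))
        if _in_grid(prev, shape):
            continue  # not a line start
        # walk the full line, RLE over (in-mask, level)
        seq = []
        p = start
        while _in_grid(p, shape):
            seq.append((bool(mask[p]), int(levels[p])))
            p = tuple(a + o for a, o in zip(p, direction))
        i = 0
        while i < len(seq):
            inm, g = seq[i]
            j = i
            while j < len(seq) and seq[j] == (inm, g):
                j += 1
            if inm:
                runs.append((g, j - i))
            i = j
    return runs


def naive_glrlm_features(levels, mask):
    runs = []
    for d in DIRECTIONS_13:
        runs.extend(naive_runs(levels, mask, d))
    n_runs = len(runs)
    assert n_runs > 0
    n_vox = int(mask.sum())
    feats = {
        "GLRLM_SRE": sum(1.0 / r**2 for _, r in runs) / n_runs,
        "GLRLM_LRE": sum(float(r**2) for _, r in runs) / n_runs,
        "GLRLM_LGRE": sum(1.0 / g**2 for g, _ in runs) / n_runs,
        "GLRLM_HGRE": sum(float(g**2) for g, _ in runs) / n_runs,
        "GLRLM_SRLGE": sum(1.0 / (g**2 * r**2) for g, r in runs) / n_runs,
        "GLRLM_SRHGE": sum(g**2 / r**2 for g, r in runs) / n_runs,
        "GLRLM_LRLGE": sum(r**2 / g**2 for g, r in runs) / n_runs,
        "GLRLM_LRHGE": sum(float(g**2 * r**2) for g, r in runs) / n_runs,
        "GLRLM_RP": n_runs / (n_vox * 13.0),
    }
    by_g = defaultdict(int)
    by_r = defaultdict(int)
    for g, r in runs:
        by_g[g] += 1
        by_r[r] += 1
    feats["GLRLM_GLNU"] = sum(v**2 for v in by_g.values()) / n_runs
    feats["GLRLM_RLNU"] = sum(v**2 for v in by_r.values()) / n_runs
    return feats


# --- GLSZM -----------------------------------------------------------------


def naive_zones(levels, mask):
    """All (level, size) zones by BFS flood fill with 26-connectivity."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p in itertools.product(*[range(s) for s in shape]):
        if not mask[p] or seen[p]:
            continue
        g = int(levels[p])
        size = 0
        queue = deque([p])
        seen[p] = True
        while queue:
            q = queue.popleft()
            size += 1
            for off in OFFSETS_26:
                r = tuple(a + o for a, o in zip(q, off))
                if _in_grid(r, shape) and mask[r] and not seen[r] and int(levels[r]) == g:
                    seen[r] = True
                    queue.append(r)
        zones.append((g, size))
    return zones


def naive_glszm_features(levels, mask):
    zones = naive_zones(levels, mask)
    nz = len(zones)
    assert nz > 0
    n_vox = int(mask.sum())
    feats = {
        "GLZLM_SZE": sum(1.0 / s**2 for _, s in zones) / nz,
        "GLZLM_LZE": sum(float(s**2) for _, s in zones) / nz,
        "GLZLM_LGZE": sum(1.0 / g**2 for g, _ in zones) / nz,
        "GLZLM_HGZE": sum(float(g**2) for g, _ in zones) / nz,
        "GLZLM_SZLGE": sum(1.0 / (g**2 * s**2) for g, s in zones) / nz,
        "GLZLM_SZHGE": sum(g**2 / s**2 for g, s in zones) / nz,
        "GLZLM_LZLGE": sum(s**2 / g**2 for g, s in zones) / nz,
        "GLZLM_LZHGE": sum(float(g**2 * s**2) for g, s in zones) / nz,
        "GLZLM_ZP": nz / n_vox,
    }
    by_g = defaultdict(int)
    by_s = defaultdict(int)
    for g, s in zones:
        by_g[g] += 1
        by_s[s] += 1
    feats["GLZLM_GLNU"] = sum(v**2 for v in by_g.values()) / nz
    feats["GLZLM_ZLNU"] = sum(v**2 for v in by_s.values()) / nz
    return feats


# --- NGLDM -----------------------------------------------------------------


def naive_ngldm_features(levels, mask, coarseness_cap=1.0e6):
    shape = levels.shape
    per_voxel = []  # (g, |g - neighbour mean|)
    for p in itertools.product(*[range(s) for s in shape]):
        if not mask[p]:
            continue
        nb = []
        for off in OFFSETS_26:
            q = tuple(a + o for a, o in zip(p, off))
            if _in_grid(q, shape) and mask[q]:
                nb.append(int(levels[q]))
        if not nb:
            continue
        per_voxel.append((int(levels[p]), abs(int(levels[p]) - sum(nb) / len(nb))))
    n = len(per_voxel)
    assert n > 0
    by_g = defaultdict(lambda: [0, 0.0])
    for g, d in per_voxel:
        by_g[g][0] += 1
        by_g[g][1] += d
    gs = sorted(by_g)
    p_g = {g: by_g[g][0] / n for g in gs}
    s_g = {g: by_g[g][1] for g in gs}

    ps = sum(p_g[g] * s_g[g] for g in gs)
    coarse = min(1.0 / ps if ps > 0 else coarseness_cap, coarseness_cap)
    if len(gs) > 1:
        ng = len(gs)
        contrast = (
            sum(p_g[a] * p_g[b] * (a - b) ** 2 for a in gs for b in gs)
            / (ng * (ng - 1))
            * (sum(s_g.values()) / n)
        )
        denom = sum(abs(a * p_g[a] - b * p_g[b]) for a in gs for b in gs)
        busy = ps / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busy = 0.0
    return {"NGLDM_Coarseness": coarse, "NGLDM_Contrast": contrast, "NGLDM_Busyness": busy}


# --- histogram -------------------------------------------------------------


def naive_histogram_features(levels, mask, n_levels=64):
    g = [int(v) for v in levels[mask]]
    n = len(g)
    assert n > 0
    mu = sum(g) / n
    m2 = sum((x - mu) ** 2 for x in g) / n
    if m2 > 0:
        m3 = sum((x - mu) ** 3 for x in g) / n
        m4 = sum((x - mu) ** 4 for x in g) / n
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    else:
        skew = kurt = 0.0
    counts = defaultdict(int)
    for x in g:
        counts[x] += 1
    probs = [c / n for c in counts.values()]
    return {
        "HISTO_Skewness": skew,
        "HISTO_Kurtosis": kurt,
        "HISTO_EntropyLog2": -sum(p * math.log2(p) for p in probs),
        "HISTO_EntropyLog10": -sum(p * math.log10(p) for p in probs),
        "HISTO_Energy": sum(p * p for p in probs),
    }
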