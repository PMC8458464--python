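"""Feature selection: correlation pruning, rank-sum screening, ROC cutoffs.

Stages mirror the analysis order of a radiomics survival study: redundant
features (|Spearman rho| > 0.8) are pruned first, the survivors are screened
against vital status with two-sided Wilcoxon rank-sum tests under a
Bonferroni family threshold, and each significant feature is dichotomized at
the Youden-optimal ROC cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CutoffResult",
    "spearman_prune",
    "wilcoxon_select",
    "youden_cutoff",
]


@dataclass(frozen=True)
class CutoffResult:
    """A Youden-optimal dichotomization threshold with its ROC summary."""

    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    auc: float
    positive_direction: str = "high_is_positive"

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden_j": self.youden_j,
            "auc": self.auc,
            "positive_direction": self.positive_direction,
        }


def spearman_prune(table: pd.DataFrame, threshold: float = 0.8) -> list[str]:
    """Greedy redundancy pruning on pairwise |Spearman rho|.

    Features are visited in column order; a feature is dropped when its
    absolute Spearman correlation with any earlier *kept* feature exceeds
    ``threshold``.  Deterministic and order-stable: of a correlated pair the
    earlier feature survives.
    """
    feats = list(table.columns)
    if len(feats) < 2:
        raise ValueError("pruning needs at least 2 features")
    x = table.to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("pruning needs at least 3 samples")
    const = np.all(x == x[0], axis=0)
    if const.any():
        bad = [f for f, c in zip(feats, const) if c]
        raise ValueError(f"constant features have undefined rank correlation: {bad}")

    rho = stats.spearmanr(x).statistic
    rho = np.atleast_2d(rho)
    kept: list[int] = []
    for j in range(len(feats)):
        if all(abs(rho[j, k]) <= threshold for k in kept):
            kept.append(j)
    return [feats[j] for j in kept]


def wilcoxon_select(
    table: pd.DataFrame,
    group_labels,
    family_alpha: float = 0.05,
) -> tuple[pd.Series, list[str], float]:
    """Two-sided Wilcoxon rank-sum screen with Bonferroni control.

    ``group_labels`` is binary (0/1) per row.  Returns per-feature p-values,
    the selected feature names (p < family_alpha / m, with m the number of
    features tested), and the threshold itself.  The exact null distribution
    is enumerated when both groups have <= 10 samples and the feature has no
    ties; otherwise the tie-corrected normal approximation is used.
    """
    labels = np.asarray(group_labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("group labels must be binary 0/1")
    g0 = table.loc[labels == 0]
    g1 = table.loc[labels == 1]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both groups must be nonempty")

    pvals = {}
    for feat in table.columns:
        a = g0[feat].to_numpy(dtype=float)
        b = g1[feat].to_numpy(dtype=float)
        exact_ok = len(a) <= 10 and len(b) <= 10 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        method = "exact" if exact_ok else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        pvals[feat] = float(res.pvalue)
    p = pd.Series(pvals, name="p_value")
    m = len(table.columns)
    threshold = family_alpha / m
    selected = [f for f in table.columns if p[f] < threshold]
    return p, selected, threshold


def youden_cutoff(scores, binary_outcome) -> CutoffResult:
    """Youden-optimal ROC threshold for a score predicting a binary outcome.

    Direction is fixed to high-is-positive (larger score predicts the event).
    Candidate thresholds are midpoints between consecutive sorted unique
    scores; ties on J are broken toward higher specificity, then the lower
    threshold.  AUC is the tie-corrected rank (Mann-Whitney) statistic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_outcome).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and outcome must have the same length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")

    u = stats.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided").statistic
    auc = float(u) / (n1 * n0)

    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValueError("scores are constant: no threshold exists")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0

    best: CutoffResult | None = None
    for t in candidates:
        pred = s > t
        sens = float((pred & (y == 1)).sum() / n1)
        spec = float((~pred & (y == 0)).sum() / n0)
        j = sens + spec - 1.0
        cand = CutoffResult(float(t), sens, spec, j, auc)
        if (
            best is None
            or j > best.youden_j + 1e-12
            or (abs(j - best.youden_j) <= 1e-12 and spec > best.specificity + 1e-12)
        ):
            best = cand
    return best
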