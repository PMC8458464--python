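"""Parametric empirical-Bayes (ComBat-style) batch harmonization.

The location-scale model ``y_ijf = alpha_f + gamma_if + delta_if * eps`` is
fitted per feature across scanner batches with no biological covariates.
Per-batch location and scale estimates are shrunk by empirical-Bayes priors
(normal on locations, inverse-gamma on squared scales) with moment-matched
hyperparameters and the standard fixed-point iteration.

Sample moments use the 1/n convention throughout so that fitting and
applying on a single batch is an exact identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["HarmonizationModel", "fit_combat", "apply_combat"]

_TOL = 1e-8
_MAX_ITER = 500


@dataclass
class HarmonizationModel:
    """Fitted per-feature standardization and per-batch EB parameters."""

    feature_names: list[str]
    batch_labels: list[str]
    grand_mean: np.ndarray  # (n_features,)
    pooled_sd: np.ndarray  # (n_features,)
    gamma_star: np.ndarray  # (n_batches, n_features) EB location
    delta_star_sq: np.ndarray  # (n_batches, n_features) EB squared scale

    def _batch_index(self, label: str) -> int:
        try:
            return self.batch_labels.index(str(label))
        except ValueError:
            raise KeyError(f"batch label {label!r} was not seen during fitting") from None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "batch_labels": self.batch_labels,
            "grand_mean": self.grand_mean.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star_sq": self.delta_star_sq.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "HarmonizationModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            feature_names=list(payload["feature_names"]),
            batch_labels=list(payload["batch_labels"]),
            grand_mean=np.asarray(payload["grand_mean"], dtype=float),
            pooled_sd=np.asarray(payload["pooled_sd"], dtype=float),
            gamma_star=np.asarray(payload["gamma_star"], dtype=float),
            delta_star_sq=np.asarray(payload["delta_star_sq"], dtype=float),
        )


def _as_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    feats = list(table.columns)
    x = table.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature table contains non-finite values")
    return x, feats


def fit_combat(table: pd.DataFrame, batch_labels) -> HarmonizationModel:
    """Fit the harmonization model on a samples x features table.

    ``batch_labels`` is one label per row.  Every batch needs at least two
    samples; features with zero pooled variance are rejected by name.
    """
    x, feats = _as_matrix(table)
    batches = np.asarray([str(b) for b in batch_labels])
    if len(batches) != x.shape[0]:
        raise ValueError("batch_labels length does not match table rows")
    labels = sorted(set(batches))
    groups = [np.flatnonzero(batches == b) for b in labels]
    n_i = np.array([len(g) for g in groups])
    if np.any(n_i < 2):
        bad = [b for b, n in zip(labels, n_i) if n < 2]
        raise ValueError(f"batches with fewer than 2 samples cannot be harmonized: {bad}")
    n_total = x.shape[0]

    # precision-weighted grand mean and pooled residual SD (1/n convention)
    batch_means = np.stack([x[g].mean(axis=0) for g in groups])  # (k, f)
    grand_mean = (n_i[:, None] / n_total * batch_means).sum(axis=0)
    resid = x.copy()
    for g, bm in zip(groups, batch_means):
        resid[g] -= bm
    pooled_var = (resid**2).mean(axis=0)
    zero_var = pooled_var <= 0
    if np.any(zero_var):
        bad_feats = [f for f, z in zip(feats, zero_var) if z]
        raise ValueError(f"zero-variance features cannot be harmonized: {bad_feats}")
    pooled_sd = np.sqrt(pooled_var)

    z = (x - grand_mean) / pooled_sd
    gamma_hat = np.stack([z[g].mean(axis=0) for g in groups])
    delta_hat_sq = np.stack([z[g].var(axis=0) for g in groups])  # ddof=0

    gamma_star = np.empty_like(gamma_hat)
    delta_star_sq = np.empty_like(delta_hat_sq)
    for bi, g in enumerate(groups):
        gamma_star[bi], delta_star_sq[bi] = _eb_shrink(
            z[g], gamma_hat[bi], delta_hat_sq[bi], len(g)
        )

    return HarmonizationModel(
        feature_names=feats,
        batch_labels=labels,
        grand_mean=grand_mean,
        pooled_sd=pooled_sd,
        gamma_star=gamma_star,
        delta_star_sq=delta_star_sq,
    )


def _eb_shrink(z_batch, gamma_hat, delta_hat_sq, n):
    """EB posterior location/scale for one batch (vectorized over features).

    Hyperparameters are moment-matched across features; degenerate
    hyperpriors (no spread across features, e.g. a single batch or a single
    feature) fall back to the raw estimates.
    """
    g_bar = gamma_hat.mean()
    t2 = gamma_hat.var(ddof=1) if gamma_hat.size > 1 else 0.0
    m = delta_hat_sq.mean()
    s2 = delta_hat_sq.var(ddof=1) if delta_hat_sq.size > 1 else 0.0

    if t2 <= 0 and s2 <= 0:
        return gamma_hat.copy(), delta_hat_sq.copy()
    if s2 <= 0:
        # scale prior degenerate: shrink locations only
        d_star = delta_hat_sq.copy()
        g_star = (n * t2 * gamma_hat + d_star * g_bar) / (n * t2 + d_star)
        return g_star, d_star

    a = (2.0 * s2 + m**2) / s2
    b = (m * s2 + m**3) / s2

    g_old = gamma_hat.copy()
    d_old = delta_hat_sq.copy()
    for _ in range(_MAX_ITER):
        if t2 > 0:
            g_new = (n * t2 * gamma_hat + d_old * g_bar) / (n * t2 + d_old)
        else:
            g_new = np.full_like(gamma_hat, g_bar)
        sum2 = ((z_batch - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
        if change < _TOL:
            break
    return g_old, d_old


def apply_combat(model: HarmonizationModel, table: pd.DataFrame, batch_labels) -> pd.DataFrame:
    """Harmonize a samples x features table with a fitted model.

    Adjusted value: ``y* = sd_f * (z - gamma*_if) / delta*_if + mean_f``.
    The transform is affine with positive slope per batch and feature, so
    within-batch ranks are preserved; harmonized values of positive-valued
    features may legitimately be negative.
    """
    missing = [f for f in model.feature_names if f not in table.columns]
    if missing:
        raise KeyError(f"features missing from table: {missing}")
    x = table[model.feature_names].to_numpy(dtype=float)
    batches = [str(b) for b in batch_labels]
    if len(batches) != x.shape[0]:
        raise ValueError("batch_labels length does not match table rows")
    idx = np.array([model._batch_index(b) for b in batches])

    z = (x - model.grand_mean) / model.pooled_sd
    adj = (z - model.gamma_star[idx]) / np.sqrt(model.delta_star_sq[idx])
    out = adj * model.pooled_sd + model.grand_mean
    result = table.copy()
    result[model.feature_names] = out
    return result
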