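"""Kaplan-Meier / log-rank / Cox machinery and the composite metabolic score.

The composite score combines two binary risk indicators (total metabolic
tumour volume and long-zone emphasis, each dichotomized at its cutoff) into
three tiers: low (0 risk variables), intermediate (1), high (2).  The risk
comparison is strictly ``>`` the cutoff by default.

Cox models are fitted with lifelines (Efron tie handling); the product-limit
estimator is implemented directly so worked examples stay independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "KaplanMeierCurve",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "CoxResult",
    "composite_score",
    "RiskStratification",
    "stratify_cohort",
    "plot_km",
    "RISK_GROUPS",
]

RISK_GROUPS = ("low", "intermediate", "high")


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Right-continuous product-limit step function."""

    times: np.ndarray  # event times where the curve drops
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    survival_rate_at_end: float

    def at(self, t: float) -> float:
        """S(t) for arbitrary t >= 0."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events, end_time: float | None = None) -> KaplanMeierCurve:
    """Product-limit survival estimate under right censoring.

    ``survival_rate_at_end`` is the estimate evaluated at ``end_time``
    (default: the largest observed time in the supplied data; pass the
    cohort-wide maximum to compare groups at a common horizon).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    if t.size == 0:
        raise ValueError("no observations")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if set(np.unique(e)) - {0, 1}:
        raise ValueError("event flags must be 0/1")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    surv, at_risk = [], []
    s = 1.0
    for et in event_times:
        n_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
    curve_t = event_times
    curve_s = np.asarray(surv)
    curve_n = np.asarray(at_risk, dtype=int)
    end = float(t.max()) if end_time is None else float(end_time)
    rate = 1.0 if curve_t.size == 0 else (
        1.0 if end < curve_t[0] else float(curve_s[np.searchsorted(curve_t, end, side="right") - 1])
    )
    return KaplanMeierCurve(curve_t, curve_s, curve_n, rate)


def logrank_test(group_assignments, times, events) -> tuple[float, float]:
    """Log-rank test across >= 2 groups; returns (chi-square, p)."""
    g = np.asarray(group_assignments)
    if len(np.unique(g)) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(np.asarray(times, float), g, np.asarray(events).astype(int))
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    """Per-variable hazard ratios with Wald CIs from a Cox fit."""

    summary: pd.DataFrame  # index: variable; columns: hr, ci_low, ci_high, p, coef

    def hr(self, var: str) -> float:
        return float(self.summary.loc[var, "hr"])

    def p(self, var: str) -> float:
        return float(self.summary.loc[var, "p"])


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str) -> pd.DataFrame:
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return out


def cox_fit(
    covariate_table: pd.DataFrame,
    times,
    events,
    multivariate_gate_p: float = 0.05,
) -> tuple[CoxResult, CoxResult | None, list[str]]:
    """Univariate Cox screens plus a gated multivariate model.

    Each column of ``covariate_table`` (numeric; categoricals must be coded
    as dummies beforehand, sharing a common prefix ``name:``) is first fitted
    alone.  Variables whose univariate p-value is below
    ``multivariate_gate_p`` enter the multivariate model; for dummy-coded
    groups the smallest coefficient p-value gates the whole group.

    Returns (univariate result, multivariate result or None, gated names).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    base = pd.DataFrame({"_time": t, "_event": e}, index=covariate_table.index)

    groups: dict[str, list[str]] = {}
    for col in covariate_table.columns:
        key = col.split(":", 1)[0]
        groups.setdefault(key, []).append(col)

    uni_rows = []
    gated: list[str] = []
    for key, cols in groups.items():
        df = pd.concat([covariate_table[cols], base], axis=1)
        summary = _fit_cox(df, "_time", "_event")
        uni_rows.append(summary)
        if summary["p"].min() < multivariate_gate_p:
            gated.append(key)
    univariate = CoxResult(pd.concat(uni_rows))

    multivariate = None
    if gated:
        cols = [c for k in gated for c in groups[k]]
        df = pd.concat([covariate_table[cols], base], axis=1)
        multivariate = CoxResult(_fit_cox(df, "_time", "_event"))
    return univariate, multivariate, gated


def composite_score(
    total_mtv_cm3: float,
    lze: float,
    mtv_cutoff: float = 5.6,
    lze_cutoff: float = -437.0,
    strict: bool = True,
) -> tuple[int, int, str]:
    """Two-indicator metabolic risk score: (mtv_risk, lze_risk, group).

    ``strict`` uses ``value > cutoff`` for risk (default); ``False`` uses
    ``>=``.  Missing values are rejected, never imputed.
    """
    if not (np.isfinite(total_mtv_cm3) and np.isfinite(lze)):
        raise ValueError("composite score requires finite MTV and LZE values")
    if strict:
        mtv_risk = int(total_mtv_cm3 > mtv_cutoff)
        lze_risk = int(lze > lze_cutoff)
    else:
        mtv_risk = int(total_mtv_cm3 >= mtv_cutoff)
        lze_risk = int(lze >= lze_cutoff)
    return mtv_risk, lze_risk, RISK_GROUPS[mtv_risk + lze_risk]


@dataclass
class RiskStratification:
    """Per-patient risk assignment with per-group survival summaries."""

    assignments: pd.DataFrame  # patient_id, mtv_risk, lze_risk, group
    group_sizes: dict[str, int]
    km_curves: dict[str, KaplanMeierCurve]
    survival_rates: dict[str, float]
    pairwise_logrank: dict[str, float]  # "low_vs_high" -> p
    group_hazard_ratios: dict[str, dict]  # group vs rest
    warnings: list[str] = field(default_factory=list)

    def to_report(self) -> dict:
        return {
            "group_sizes": self.group_sizes,
            "survival_rates": self.survival_rates,
            "pairwise_logrank_p": self.pairwise_logrank,
            "group_hazard_ratios": self.group_hazard_ratios,
            "warnings": self.warnings,
        }


def stratify_cohort(
    cohort: pd.DataFrame,
    mtv_cutoff: float = 5.6,
    lze_cutoff: float = -437.0,
    mtv_col: str = "total_mtv_cm3",
    lze_col: str = "GLZLM_LZE",
    time_col: str = "os_months",
    event_col: str = "event",
    strict: bool = True,
) -> RiskStratification:
    """Assign the 3-tier composite score and summarize survival per tier.

    Survival rates are read off each group's KM curve at the largest
    observed time in the whole cohort.  Pairwise log-rank tests and
    group-vs-rest Cox hazard ratios skip groups that are empty or too small
    to fit, with a warning recorded in the report.
    """
    notes: list[str] = []
    rows = []
    for _, r in cohort.iterrows():
        mtv_risk, lze_risk, group = composite_score(
            r[mtv_col], r[lze_col], mtv_cutoff, lze_cutoff, strict=strict
        )
        rows.append(
            {
                "patient_id": r.get("patient_id", _),
                "mtv_risk": mtv_risk,
                "lze_risk": lze_risk,
                "group": group,
            }
        )
    assign = pd.DataFrame(rows, index=cohort.index)

    times = cohort[time_col].to_numpy(dtype=float)
    events = cohort[event_col].to_numpy()
    end_time = float(times.max())

    sizes = {g: int((assign["group"] == g).sum()) for g in RISK_GROUPS}
    curves: dict[str, KaplanMeierCurve] = {}
    rates: dict[str, float] = {}
    for g in RISK_GROUPS:
        sel = (assign["group"] == g).to_numpy()
        if sel.sum() == 0:
            notes.append(f"group {g!r} is empty; skipped")
            continue
        curves[g] = km_estimate(times[sel], events[sel], end_time=end_time)
        rates[g] = curves[g].survival_rate_at_end

    pairwise: dict[str, float] = {}
    for a, b in (("low", "intermediate"), ("low", "high"), ("intermediate", "high")):
        sel = assign["group"].isin([a, b]).to_numpy()
        if sizes.get(a, 0) == 0 or sizes.get(b, 0) == 0:
            notes.append(f"pairwise log-rank {a} vs {b} skipped (empty group)")
            continue
        _, p = logrank_test(assign.loc[sel, "group"], times[sel], events[sel])
        pairwise[f"{a}_vs_{b}"] = p

    hrs: dict[str, dict] = {}
    for g in RISK_GROUPS:
        n_g = sizes.get(g, 0)
        if n_g == 0 or n_g == len(cohort):
            notes.append(f"group-vs-rest HR for {g!r} skipped (degenerate split)")
            continue
        indicator = (assign["group"] == g).astype(float)
        df = pd.DataFrame({"in_group": indicator, "_time": times, "_event": events})
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                summary = _fit_cox(df, "_time", "_event")
            hrs[g] = {
                "hr": float(summary.loc["in_group", "hr"]),
                "ci_low": float(summary.loc["in_group", "ci_low"]),
                "ci_high": float(summary.loc["in_group", "ci_high"]),
                "p": float(summary.loc["in_group", "p"]),
            }
        except Exception as exc:  # convergence failures on tiny groups
            notes.append(f"group-vs-rest HR for {g!r} failed: {exc}")

    return RiskStratification(
        assignments=assign,
        group_sizes=sizes,
        km_curves=curves,
        survival_rates=rates,
        pairwise_logrank=pairwise,
        group_hazard_ratios=hrs,
        warnings=notes,
    )


def plot_km(strat: RiskStratification, path: str, title: str = "Overall survival by risk group") -> None:
    """Save a simple step plot of the per-group KM curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for g, curve in strat.km_curves.items():
        xs = np.concatenate([[0.0], np.repeat(curve.times, 2)])
        ys = np.concatenate([[1.0, 1.0], np.repeat(curve.survival, 2)[:-1]]) if curve.times.size else np.array([1.0])
        if curve.times.size:
            ax.plot(xs, ys, label=f"{g} (n={len(curve.n_at_risk)} drops)", drawstyle="default")
        else:
            ax.plot([0, 1], [1, 1], label=g)
    ax.set_xlabel("months")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1.05)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
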