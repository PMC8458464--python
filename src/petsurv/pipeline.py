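"""End-to-end orchestration of the prognostic analysis.

Stage order (mirroring the study design): feature table ingest (or image
segmentation + extraction) -> ComBat harmonization -> Spearman pruning ->
Wilcoxon screen against vital status -> Youden ROC cutoffs -> univariate Cox
on dichotomized features plus clinical covariates -> p-gated multivariate
Cox -> two-feature composite score -> 3-tier Kaplan-Meier stratification.

The run report is a plain JSON-serializable dict; a fixed seed and config
yield an identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .harmonization import apply_combat, fit_combat
from .radiomics.extract import extract_features
from .radiomics.registry import ALL_FEATURES
from .segmentation import lesion_metrics, segment_lesion, select_hottest, total_mtv
from .selection import spearman_prune, wilcoxon_select, youden_cutoff
from .survival import cox_fit, stratify_cohort
from .volume import read_volume

logger = logging.getLogger("petsurv.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "extract_cohort_features", "analyze_table"]

#: Candidate prognostic columns, in canonical pruning order (total MTV first
#: so it survives pruning against its own correlates).
CANDIDATE_FEATURES: tuple[str, ...] = ("total_mtv_cm3",) + ALL_FEATURES

CLINICAL_COLS = ("age", "sex", "m_status")


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    cohort_csv: str | None = None  # precomputed feature table
    image_manifest: str | None = None  # CSV: patient_id, volume_path, seed voxels, clinical
    harmonize: bool = True
    harmonize_mtv: bool = False  # total MTV stays in physical units by default
    prune_threshold: float = 0.8
    family_alpha: float = 0.05
    gate_p: float = 0.05
    cutoff_mode: str = "youden"  # "youden" | "fixed"
    fixed_cutoffs: dict = field(default_factory=dict)  # feature -> threshold
    score_strict: bool = True
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        for name, v in (("prune_threshold", self.prune_threshold), ("family_alpha", self.family_alpha), ("gate_p", self.gate_p)):
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.cutoff_mode not in ("youden", "fixed"):
            raise ValueError("cutoff_mode must be 'youden' or 'fixed'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def extract_cohort_features(manifest: pd.DataFrame) -> pd.DataFrame:
    """Segment and extract features for every patient of an image manifest.

    ``manifest`` rows need ``patient_id``, ``volume_path``, ``seeds`` (a
    ``;``-separated list of ``i,j,k`` voxel triples) and may carry clinical
    columns (age, sex, m_status, batch, os_months, event), which are passed
    through.  Features come from the hottest lesion; total MTV sums all
    segmented lesions.
    """
    rows = []
    for _, r in manifest.iterrows():
        volume = read_volume(r["volume_path"], batch_label=str(r.get("batch", "")))
        seeds = [tuple(int(x) for x in s.split(",")) for s in str(r["seeds"]).split(";")]
        masks = [segment_lesion(volume, seed, lesion_id=i + 1) for i, seed in enumerate(seeds)]
        metrics = [lesion_metrics(volume, m) for m in masks]
        hottest = select_hottest(metrics)
        features = extract_features(volume, masks[hottest].mask)
        row = {
            "patient_id": r["patient_id"],
            "total_mtv_cm3": total_mtv(metrics),
            **features,
        }
        for col in CLINICAL_COLS + ("batch", "os_months", "event"):
            if col in manifest.columns:
                row[col] = r[col]
        rows.append(row)
    return pd.DataFrame(rows)


def _cox_design(cohort: pd.DataFrame, dichotomized: pd.DataFrame) -> pd.DataFrame:
    """Dichotomized features + age (continuous), sex and M-status dummies."""
    design = dichotomized.copy()
    if "age" in cohort.columns:
        design["age"] = cohort["age"].astype(float)
    if "sex" in cohort.columns:
        design["sex"] = (cohort["sex"].astype(str) == "M").astype(float)
    if "m_status" in cohort.columns:
        # M1a is the reference level
        for level in ("M1b", "M1c", "M1d"):
            design[f"m_status:{level}"] = (cohort["m_status"].astype(str) == level).astype(float)
    # constant covariates carry no information and break the fit
    constant = [c for c in design.columns if design[c].nunique() < 2]
    return design.drop(columns=constant)


def analyze_table(cohort: pd.DataFrame, config: PipelineConfig) -> dict:
    """Run the statistical pipeline on a feature-level cohort table."""
    report: dict = {"config": asdict(config), "stages": {}, "status": "complete"}
    cohort = cohort.reset_index(drop=True)
    features_present = [f for f in CANDIDATE_FEATURES if f in cohort.columns]
    if not features_present:
        raise ValueError("cohort table carries none of the candidate features")
    for col in ("os_months", "event"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table is missing required column {col!r}")

    # --- harmonization ------------------------------------------------
    working = cohort.copy()
    if config.harmonize:
        if "batch" not in cohort.columns:
            raise ValueError("harmonization requested but no 'batch' column present")
        to_harmonize = [f for f in features_present if f in ALL_FEATURES]
        if config.harmonize_mtv and "total_mtv_cm3" in features_present:
            to_harmonize = ["total_mtv_cm3"] + to_harmonize
        model = fit_combat(cohort[to_harmonize], cohort["batch"])
        working[to_harmonize] = apply_combat(model, cohort[to_harmonize], cohort["batch"])[to_harmonize]
        report["stages"]["harmonization"] = {
            "applied": True,
            "features": to_harmonize,
            "batches": model.batch_labels,
        }
        logger.info("harmonized %d features across %d batches", len(to_harmonize), len(model.batch_labels))
    else:
        report["stages"]["harmonization"] = {"applied": False}

    # --- pruning ------------------------------------------------------
    kept = spearman_prune(working[features_present], threshold=config.prune_threshold)
    report["stages"]["pruning"] = {
        "kept": kept,
        "dropped": [f for f in features_present if f not in kept],
    }
    logger.info("pruning kept %d of %d features", len(kept), len(features_present))

    # --- Wilcoxon screen against vital status -------------------------
    pvals, selected, bonf = wilcoxon_select(
        working[kept], working["event"], family_alpha=config.family_alpha
    )
    report["stages"]["selection"] = {
        "m_tested": len(kept),
        "bonferroni_threshold": bonf,
        "p_values": {f: float(pvals[f]) for f in kept},
        "selected": selected,
    }
    if not selected:
        report["status"] = "no_significant_features"
        logger.info("no feature passed the Bonferroni threshold %.3g", bonf)
        return report

    # --- Youden cutoffs ----------------------------------------------
    cutoffs: dict[str, float] = {}
    cutoff_details: dict[str, dict] = {}
    for feat in selected:
        if config.cutoff_mode == "fixed" and feat in config.fixed_cutoffs:
            cutoffs[feat] = float(config.fixed_cutoffs[feat])
            cutoff_details[feat] = {"threshold": cutoffs[feat], "mode": "fixed"}
        else:
            res = youden_cutoff(working[feat].to_numpy(), working["event"].to_numpy())
            cutoffs[feat] = res.threshold
            cutoff_details[feat] = res.to_dict()
    report["stages"]["cutoffs"] = cutoff_details

    # --- Cox models ---------------------------------------------------
    dich = pd.DataFrame(
        {f: (working[f] > cutoffs[f]).astype(float) for f in selected}, index=working.index
    )
    design = _cox_design(working, dich)
    uni, multi, gated = cox_fit(
        design, working["os_months"], working["event"], multivariate_gate_p=config.gate_p
    )
    report["stages"]["cox_univariate"] = uni.summary.to_dict(orient="index")
    report["stages"]["cox_multivariate"] = (
        multi.summary.to_dict(orient="index") if multi is not None else None
    )
    report["stages"]["cox_gated_variables"] = gated

    # --- composite score ---------------------------------------------
    # the two selected features with the largest univariate Cox effect
    gated_feats = [f for f in selected if f in gated]
    score_feats = sorted(
        gated_feats or selected,
        key=lambda f: abs(float(uni.summary.loc[f, "coef"])),
        reverse=True,
    )[:2]
    if len(score_feats) < 2:
        report["status"] = "insufficient_features_for_score"
        report["stages"]["score"] = {"features": score_feats}
        return report
    mtv_like, lze_like = score_feats
    strat = stratify_cohort(
        working,
        mtv_cutoff=cutoffs[mtv_like],
        lze_cutoff=cutoffs[lze_like],
        mtv_col=mtv_like,
        lze_col=lze_like,
        strict=config.score_strict,
    )
    report["stages"]["score"] = {
        "features": list(score_feats),
        "cutoffs": {f: cutoffs[f] for f in score_feats},
    }
    report["stages"]["stratification"] = strat.to_report()
    report["_stratification"] = strat  # in-memory handle, stripped before JSON
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline per the configuration and return the report.

    If ``output_dir`` is set, the JSON report and per-patient assignments
    are written there.
    """
    if config.cohort_csv:
        cohort = pd.read_csv(config.cohort_csv)
    elif config.image_manifest:
        manifest = pd.read_csv(config.image_manifest)
        cohort = extract_cohort_features(manifest)
    else:
        raise ValueError("config must provide cohort_csv or image_manifest")

    report = analyze_table(cohort, config)
    strat = report.pop("_stratification", None)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        if strat is not None:
            strat.assignments.to_csv(out / "assignments.csv", index=False)
    return report
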