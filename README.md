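# petsurv

A tested, reusable implementation of a baseline ¹⁸F-FDG-PET prognostic
radiomics pipeline: seeded lesion segmentation at 40% of SUVmax with total
metabolic tumour volume (MTV), 41 conventional / histogram / texture
features (GLCM, GLRLM, NGLDM, GLZLM — including long-zone emphasis, LZE),
parametric empirical-Bayes (ComBat-style) multi-scanner harmonization,
feature selection with Spearman pruning, Wilcoxon screening and
Youden-index ROC cutoffs, Cox / Kaplan–Meier survival modelling, and a
composite 3-tier metabolic risk score.

Everything is exercised on synthetic inputs: textured PET phantoms with
scanner-dependent smoothing/bias/noise, and feature-level cohorts with
planted proportional-hazards survival structure. No downloads required.

## Layout

| module | purpose |
| --- | --- |
| `petsurv.volume` | `PetVolume` container, NIfTI I/O, SUV conversion |
| `petsurv.synthetic` | phantom generator (Gaussian-random-field lesion texture, scanner PSF/bias/noise) and cohort simulator (exponential PH survival with binary MTV/LZE risk indicators) |
| `petsurv.segmentation` | two-pass seeded 40%-of-SUVmax region growing, per-lesion metrics (MTV, SUV stats, SUVpeak, TLG), total MTV, hottest-lesion selection |
| `petsurv.radiomics` | 0–32 SUV / 64-level discretizer and the 41-feature extractor (5 conventional, 5 histogram, 6 GLCM, 11 GLRLM, 3 NGLDM, 11 GLZLM) |
| `petsurv.harmonization` | parametric EB location-scale batch harmonization (fit/apply, JSON serialization) |
| `petsurv.selection` | Spearman redundancy pruning (&#124;ρ&#124; > 0.8), Wilcoxon rank-sum screen with Bonferroni control, Youden-optimal ROC cutoffs |
| `petsurv.survival` | Kaplan–Meier, log-rank, univariate + p-gated multivariate Cox (via lifelines), composite score, 3-tier stratification report |
| `petsurv.pipeline` | end-to-end orchestration (images or feature table → stratified report), YAML config |
| `petsurv.cli` | `petsurv` command-line interface |

## CLI

```bash
# simulate a feature-level cohort (56 patients, 4 scanner batches by default)
petsurv simulate --n 300 --seed 11 --out cohort.csv

# generate a phantom volume + ground-truth masks from a YAML config
petsurv phantom --config phantom.yaml --out-volume vol.nii --out-masks masks.nii

# segment + extract features from volumes listed in a manifest CSV
petsurv extract --manifest manifest.csv --out features.csv

# harmonize feature columns across scanner batches
petsurv harmonize --features cohort.csv --batch-col batch --out harmonized.csv

# prune + screen + ROC cutoffs
petsurv select --features harmonized.csv --group-col event \
    --out-pvalues pvals.csv --out-cutoffs cutoffs.json

# composite risk score (MTV / LZE cutoffs) with KM summaries
petsurv stratify --cohort cohort.csv --mtv-cutoff 5.6 --lze-cutoff -437 \
    --out-report strat.json

# full pipeline from a YAML config
petsurv run --config pipeline.yaml --out results/
```

Cohort CSV columns: `patient_id, age, sex, m_status, batch, total_mtv_cm3`,
the 41 canonical feature names (`CONV_*`, `HISTO_*`, `GLCM_*`, `GLRLM_*`,
`NGLDM_*`, `GLZLM_*`), `os_months`, `event`. Synthetic cohorts additionally
carry `truth_*` columns (pre-batch-effect values and planted risk
indicators) which the analysis ignores.

## Conventions worth knowing

- Discretization: `level = floor(SUV / 0.5) + 1`, clamped to [1, 64]
  (absolute 0–32 SUV range; overflow clamps to the top bin).
- Texture matrices use 26-connectivity / the 13 unique 3D directions;
  GLCM and GLRLM matrices are pooled over directions before normalization.
- Harmonized features can be negative even when the raw feature is
  positive; total MTV is *not* harmonized by default (physical units).
- Composite score risk is strict `>` the cutoff; groups are
  low / intermediate / high for 0 / 1 / 2 risk variables.
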