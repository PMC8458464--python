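"""Synthetic PET phantoms and feature-level survival cohorts.

Two generators make the whole pipeline testable without any download:

* :func:`generate_phantom` builds textured hypermetabolic lesions on a
  low-uptake background.  Lesion texture is a stationary Gaussian random
  field synthesized spectrally (FFT), so its correlation length maps
  monotonically to the size of homogeneous grey-level zones.  The scanner
  point-spread function is applied before noise, then a multiplicative
  intensity bias and additive Gaussian noise emulate reconstruction
  differences between scanners.

* :func:`generate_cohort` draws a feature table with planted
  proportional-hazards structure: survival times are exponential with the
  hazard scaled by two binary risk indicators (total MTV and LZE above
  their true cutoffs), right-censored uniformly over the follow-up window.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .radiomics.registry import ALL_FEATURES
from .volume import PetVolume, Units

__all__ = [
    "ScannerProfile",
    "LesionSpec",
    "PhantomConfig",
    "CohortConfig",
    "DEFAULT_SCANNERS",
    "PLANTED_CORR_PAIR",
    "generate_phantom",
    "generate_cohort",
    "simulate_survival",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ScannerProfile:
    """Reconstruction profile of one PET system.

    ``psf_fwhm_mm`` is the Gaussian post-filter width; 0 disables smoothing
    (degenerate profile used only in tests).
    """

    name: str
    psf_fwhm_mm: float
    voxel_size_mm: tuple[float, float, float]
    intensity_bias: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be 3 positive values")
        if self.intensity_bias <= 0:
            raise ValueError("intensity_bias must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: Four scanner profiles emulating the reconstruction heterogeneity of a
#: multi-centre study (post-filter FWHM 4-5 mm, heterogeneous voxel sizes).
#: Bias and noise magnitudes are stated assumptions, not estimates.
DEFAULT_SCANNERS: tuple[ScannerProfile, ...] = (
    ScannerProfile("biograph_horizon_16", 4.0, (2.06, 2.06, 2.03), 1.00, 0.05),
    ScannerProfile("discovery_690", 4.0, (2.73, 2.73, 3.27), 1.08, 0.06),
    ScannerProfile("biograph_20_mct", 5.0, (1.59, 1.59, 3.00), 0.94, 0.04),
    ScannerProfile("biograph_6_hirez", 5.0, (4.06, 4.06, 4.00), 1.12, 0.07),
)


@dataclass(frozen=True)
class LesionSpec:
    """One spherical lesion: centre (voxel index), radius and texture."""

    center_voxel: tuple[int, int, int]
    radius_mm: float
    base_suv: float
    texture_corr_mm: float = 4.0
    texture_amp_suv: float = 0.0

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        if self.texture_corr_mm <= 0:
            raise ValueError("texture_corr_mm must be > 0")
        if self.texture_amp_suv < 0:
            raise ValueError("texture_amp_suv must be >= 0")


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int]
    background_suv: float
    lesions: tuple[LesionSpec, ...]
    scanner: ScannerProfile
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive ints")
        for les in self.lesions:
            if les.base_suv <= self.background_suv:
                raise ValueError("lesion base SUV must exceed background SUV")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        raw = yaml.safe_load(Path(path).read_text())
        scanner = ScannerProfile(
            name=raw["scanner"]["name"],
            psf_fwhm_mm=float(raw["scanner"]["psf_fwhm_mm"]),
            voxel_size_mm=tuple(raw["scanner"]["voxel_size_mm"]),
            intensity_bias=float(raw["scanner"].get("intensity_bias", 1.0)),
            noise_sd=float(raw["scanner"].get("noise_sd", 0.0)),
        )
        lesions = tuple(
            LesionSpec(
                center_voxel=tuple(l["center_voxel"]),
                radius_mm=float(l["radius_mm"]),
                base_suv=float(l["base_suv"]),
                texture_corr_mm=float(l.get("texture_corr_mm", 4.0)),
                texture_amp_suv=float(l.get("texture_amp_suv", 0.0)),
            )
            for l in raw["lesions"]
        )
        return cls(
            grid_shape=tuple(raw["grid_shape"]),
            background_suv=float(raw["background_suv"]),
            lesions=lesions,
            scanner=scanner,
            seed=int(raw.get("seed", 0)),
        )


def _sphere_mask(shape, voxel, center_vox, radius_mm) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum(((g - c) * v) ** 2 for g, c, v in zip(grids, center_vox, voxel))
    return d2 <= radius_mm**2


def _gaussian_random_field(shape, voxel, corr_mm, rng) -> np.ndarray:
    """Unit-variance stationary GRF via FFT spectral synthesis."""
    white = rng.standard_normal(shape)
    spectrum = np.fft.fftn(white)
    k2 = np.zeros(shape)
    for ax, (n, v) in enumerate(zip(shape, voxel)):
        k = 2.0 * np.pi * np.fft.fftfreq(n, d=v)
        sh = [1, 1, 1]
        sh[ax] = n
        k2 = k2 + (k.reshape(sh)) ** 2
    spectrum *= np.exp(-0.5 * k2 * corr_mm**2)
    fld = np.real(np.fft.ifftn(spectrum))
    sd = fld.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (fld - fld.mean()) / sd


def generate_phantom(
    config: PhantomConfig,
) -> tuple[PetVolume, list[np.ndarray], list[LesionSpec]]:
    """Build one textured PET phantom.

    Returns (volume, ground-truth lesion masks, lesion specs).  The masks
    mark the spherical supports before PSF smoothing.  Lesions must fit
    inside the grid and may not overlap.
    """
    scanner = config.scanner
    voxel = scanner.voxel_size_mm
    shape = config.grid_shape
    extent = [s * v for s, v in zip(shape, voxel)]
    rng = np.random.default_rng(config.seed)

    masks: list[np.ndarray] = []
    for les in config.lesions:
        center_mm = [(c + 0.5) * v for c, v in zip(les.center_voxel, voxel)]
        for cm, ext in zip(center_mm, extent):
            if cm - les.radius_mm < 0 or cm + les.radius_mm > ext:
                raise ValueError(f"lesion at {les.center_voxel} extends past the grid")
        masks.append(_sphere_mask(shape, voxel, les.center_voxel, les.radius_mm))
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if np.any(masks[i] & masks[j]):
                raise ValueError(f"lesions {i} and {j} overlap")

    vol = np.full(shape, float(config.background_suv))
    for les, mask in zip(config.lesions, masks):
        vol[mask] = les.base_suv
        if les.texture_amp_suv > 0:
            fld = _gaussian_random_field(shape, voxel, les.texture_corr_mm, rng)
            vol[mask] += les.texture_amp_suv * fld[mask]
    if scanner.psf_fwhm_mm > 0:
        sigma_vox = [scanner.psf_fwhm_mm * _FWHM_TO_SIGMA / v for v in voxel]
        vol = ndimage.gaussian_filter(vol, sigma=sigma_vox)
    vol = vol * scanner.intensity_bias
    if scanner.noise_sd > 0:
        vol = vol + rng.normal(0.0, scanner.noise_sd, size=shape)

    volume = PetVolume(
        data=vol,
        voxel_size_mm=voxel,
        units=Units.SUV,
        batch_label=scanner.name,
    )
    return volume, masks, list(config.lesions)


# ---------------------------------------------------------------------------
# feature-level cohorts


#: Nuisance feature pair planted with near-perfect rank correlation so the
#: Spearman pruning stage has a deterministic target.
PLANTED_CORR_PAIR = ("GLCM_Energy", "GLCM_Homogeneity")

_M_STATUS = ("M1a", "M1b", "M1c", "M1d")
_M_STATUS_P = (13 / 56, 5 / 56, 31 / 56, 7 / 56)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the simulated feature-level survival cohort.

    Defaults mirror the reference study design: 56 patients over 4 scanner
    batches (33/23 split across two centres), planted multivariate hazard
    ratios 4.1 (MTV indicator) and 3.7 (LZE indicator), follow-up window
    2.1-49.2 months and roughly 38% events.
    """

    n_patients: int = 56
    batch_labels: tuple[str, ...] = tuple(s.name for s in DEFAULT_SCANNERS)
    batch_proportions: tuple[float, ...] = (11 / 56, 12 / 56, 19 / 56, 14 / 56)
    mtv_distribution: tuple[float, float] = (np.log(5.6), 1.2)  # log-normal mu, sigma
    lze_distribution: tuple[float, float] = (5000.0, 8000.0)  # normal loc, scale
    batch_location_shift: tuple[float, ...] = (0.0, 0.6, -0.5, 1.0)  # in feature SDs
    batch_scale_factor: tuple[float, ...] = (1.0, 1.25, 0.85, 1.1)
    planted_log_hr_mtv: float = float(np.log(4.1))
    planted_log_hr_lze: float = float(np.log(3.7))
    true_cutoff_mtv: float = 5.6
    true_cutoff_lze: float = 5000.0
    baseline_hazard_rate: float = 0.0045  # events per month, calibrated to ~38% events
    censor_window_months: tuple[float, float] = (2.1, 49.2)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if len(self.batch_proportions) != len(self.batch_labels):
            raise ValueError("batch_proportions must match batch_labels")
        if abs(sum(self.batch_proportions) - 1.0) > 1e-9:
            raise ValueError("batch_proportions must sum to 1")
        if len(self.batch_location_shift) != len(self.batch_labels):
            raise ValueError("batch_location_shift must match batch_labels")
        if len(self.batch_scale_factor) != len(self.batch_labels):
            raise ValueError("batch_scale_factor must match batch_labels")
        if any(s <= 0 for s in self.batch_scale_factor):
            raise ValueError("batch_scale_factor entries must be > 0")
        if self.mtv_distribution[1] <= 0 or self.lze_distribution[1] <= 0:
            raise ValueError("degenerate (zero-scale) feature distributions")
        if self.baseline_hazard_rate <= 0:
            raise ValueError("baseline_hazard_rate must be > 0")
        lo, hi = self.censor_window_months
        if lo <= 0 or hi < lo:
            raise ValueError("censor_window_months must satisfy 0 < min <= max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in cls.__dataclass_fields__:
            if key in raw:
                val = raw[key]
                kwargs[key] = tuple(val) if isinstance(val, list) else val
        return cls(**kwargs)


def simulate_survival(
    risk_indicator_matrix,
    log_hrs,
    baseline_rate: float,
    censor_window,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential proportional-hazards sampling with uniform censoring.

    Hazard per subject: ``baseline_rate * exp(X @ log_hrs)`` with binary
    ``X``.  Returns (observed times in months, event flags).
    """
    x = np.asarray(risk_indicator_matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    beta = np.atleast_1d(np.asarray(log_hrs, dtype=float))
    if x.shape[1] != beta.shape[0]:
        raise ValueError(f"indicator matrix has {x.shape[1]} columns but {beta.shape[0]} log HRs")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("risk indicators must be binary")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    lo, hi = float(censor_window[0]), float(censor_window[1])
    if lo <= 0 or hi < lo:
        raise ValueError("censor window must satisfy 0 < min <= max")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rate = baseline_rate * np.exp(x @ beta)
    event_t = rng.exponential(1.0 / rate)
    censor_t = rng.uniform(lo, hi, size=len(rate)) if hi > lo else np.full(len(rate), lo)
    times = np.minimum(event_t, censor_t)
    events = (event_t <= censor_t).astype(int)
    return times, events


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw one feature-level cohort table.

    Columns: patient_id, age, sex, m_status, batch, total_mtv_cm3, the 41
    named radiomic features (with per-batch location/scale effects applied),
    os_months, event, plus ``truth_*`` columns carrying the pre-batch-effect
    values and the planted risk indicators (ignored by the pipeline).

    Total MTV carries no batch effect (it is reported in physical units).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    k = len(config.batch_labels)

    batch_idx = rng.choice(k, size=n, p=np.asarray(config.batch_proportions))
    age = rng.integers(40, 85, size=n)
    sex = rng.choice(["F", "M"], size=n)
    m_status = rng.choice(_M_STATUS, size=n, p=_M_STATUS_P)

    mu_mtv, sd_mtv = config.mtv_distribution
    raw_mtv = rng.lognormal(mean=mu_mtv, sigma=sd_mtv, size=n)
    loc_lze, scale_lze = config.lze_distribution
    raw_lze = rng.normal(loc_lze, scale_lze, size=n)

    # nuisance features: iid standard normal, one planted correlated pair
    raw_features: dict[str, np.ndarray] = {}
    nominal: dict[str, tuple[float, float]] = {}
    for name in ALL_FEATURES:
        if name == "GLZLM_LZE":
            raw_features[name] = raw_lze
            nominal[name] = (loc_lze, scale_lze)
        elif name == PLANTED_CORR_PAIR[1]:
            continue  # filled from its partner below
        else:
            raw_features[name] = rng.standard_normal(n)
            nominal[name] = (0.0, 1.0)
    partner, mirror = PLANTED_CORR_PAIR
    raw_features[mirror] = raw_features[partner] + 0.05 * rng.standard_normal(n)
    nominal[mirror] = (0.0, 1.0)

    shift = np.asarray(config.batch_location_shift)[batch_idx]
    scale = np.asarray(config.batch_scale_factor)[batch_idx]
    observed: dict[str, np.ndarray] = {}
    for name in ALL_FEATURES:
        mu_f, sd_f = nominal[name]
        observed[name] = mu_f + (raw_features[name] - mu_f) * scale + shift * sd_f

    mtv_risk = (raw_mtv > config.true_cutoff_mtv).astype(int)
    lze_risk = (raw_lze > config.true_cutoff_lze).astype(int)
    times, events = simulate_survival(
        np.column_stack([mtv_risk, lze_risk]),
        [config.planted_log_hr_mtv, config.planted_log_hr_lze],
        config.baseline_hazard_rate,
        config.censor_window_months,
        seed=rng,
    )

    table = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "m_status": m_status,
            "batch": [config.batch_labels[i] for i in batch_idx],
            "total_mtv_cm3": raw_mtv,
        }
    )
    for name in ALL_FEATURES:
        table[name] = observed[name]
    table["os_months"] = times
    table["event"] = events
    table["truth_mtv_raw"] = raw_mtv
    table["truth_lze_raw"] = raw_lze
    table["truth_mtv_risk"] = mtv_risk
    table["truth_lze_risk"] = lze_risk
    return table
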