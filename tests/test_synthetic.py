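import dataclasses

import numpy as np
import pandas as pd
import pytest

from petsurv.radiomics.registry import ALL_FEATURES
from petsurv.synthetic import (
    DEFAULT_SCANNERS,
    PLANTED_CORR_PAIR,
    CohortConfig,
    LesionSpec,
    PhantomConfig,
    ScannerProfile,
    generate_cohort,
    generate_phantom,
    simulate_survival,
)

IDEAL = ScannerProfile("ideal", 0.0, (2.0, 2.0, 2.0), 1.0, 0.0)


def phantom_config(**kw):
    defaults = dict(
        grid_shape=(24, 24, 24),
        background_suv=1.0,
        lesions=(LesionSpec((12, 12, 12), 10.0, 10.0, 4.0, 0.0),),
        scanner=IDEAL,
        seed=7,
    )
    defaults.update(kw)
    return PhantomConfig(**defaults)


class TestScannerProfiles:
    def test_four_default_profiles(self):
        assert len(DEFAULT_SCANNERS) == 4
        for s in DEFAULT_SCANNERS:
            assert 4.0 <= s.psf_fwhm_mm <= 5.0
            assert all(v > 0 for v in s.voxel_size_mm)

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            ScannerProfile("x", -1.0, (1, 1, 1))
        with pytest.raises(ValueError):
            ScannerProfile("x", 4.0, (1, 0, 1))
        with pytest.raises(ValueError):
            ScannerProfile("x", 4.0, (1, 1, 1), intensity_bias=0.0)
        with pytest.raises(ValueError):
            ScannerProfile("x", 4.0, (1, 1, 1), noise_sd=-0.1)


class TestGeneratePhantom:
    def test_degenerate_noise_free_case(self):
        volume, masks, _ = generate_phantom(phantom_config())
        np.testing.assert_allclose(volume.data[masks[0]], 10.0)
        np.testing.assert_allclose(volume.data[~masks[0]], 1.0)

    def test_sphere_mask_volume_analytic(self):
        _, masks, specs = generate_phantom(phantom_config())
        vol_mm3 = masks[0].sum() * 8.0
        assert abs(vol_mm3 - 4188.79) / 4188.79 < 0.05

    def test_seed_determinism(self):
        cfg = phantom_config(
            scanner=ScannerProfile("n", 4.0, (2.0, 2.0, 2.0), 1.0, 0.1),
            lesions=(LesionSpec((12, 12, 12), 10.0, 10.0, 4.0, 2.0),),
        )
        v1, _, _ = generate_phantom(cfg)
        v2, _, _ = generate_phantom(cfg)
        np.testing.assert_array_equal(v1.data, v2.data)
        v3, _, _ = generate_phantom(dataclasses.replace(cfg, seed=8))
        assert not np.array_equal(v1.data, v3.data)

    def test_overlapping_lesions_rejected(self):
        cfg = phantom_config(
            lesions=(
                LesionSpec((10, 12, 12), 8.0, 10.0),
                LesionSpec((13, 12, 12), 8.0, 10.0),
            )
        )
        with pytest.raises(ValueError, match="overlap"):
            generate_phantom(cfg)

    def test_lesion_past_grid_rejected(self):
        cfg = phantom_config(lesions=(LesionSpec((2, 12, 12), 10.0, 10.0),))
        with pytest.raises(ValueError, match="past the grid"):
            generate_phantom(cfg)

    def test_lesion_must_exceed_background(self):
        with pytest.raises(ValueError, match="exceed background"):
            phantom_config(lesions=(LesionSpec((12, 12, 12), 10.0, 0.5),))

    def test_ground_truth_recoverable(self):
        cfg = phantom_config(
            lesions=(
                LesionSpec((7, 7, 7), 5.0, 8.0),
                LesionSpec((17, 17, 17), 5.0, 12.0),
            )
        )
        volume, masks, specs = generate_phantom(cfg)
        assert len(masks) == len(specs) == 2
        for mask, spec in zip(masks, specs):
            assert mask[spec.center_voxel]
            assert volume.data[spec.center_voxel] == pytest.approx(spec.base_suv)

    def test_intensity_bias_scales(self):
        v1, _, _ = generate_phantom(phantom_config())
        cfg2 = phantom_config(scanner=ScannerProfile("b", 0.0, (2.0, 2.0, 2.0), 1.1, 0.0))
        v2, _, _ = generate_phantom(cfg2)
        np.testing.assert_allclose(v2.data, v1.data * 1.1)

    def test_yaml_round_trip(self, tmp_path):
        cfg_text = """
grid_shape: [24, 24, 24]
background_suv: 1.0
seed: 7
scanner:
  name: ideal
  psf_fwhm_mm: 0.0
  voxel_size_mm: [2.0, 2.0, 2.0]
lesions:
  - center_voxel: [12, 12, 12]
    radius_mm: 10.0
    base_suv: 10.0
"""
        p = tmp_path / "phantom.yaml"
        p.write_text(cfg_text)
        cfg = PhantomConfig.from_yaml(p)
        v1, _, _ = generate_phantom(cfg)
        v2, _, _ = generate_phantom(phantom_config())
        np.testing.assert_array_equal(v1.data, v2.data)


class TestSimulateSurvival:
    def test_exponential_mean_null(self):
        lam = 0.05
        x = np.zeros((20000, 1))
        times, events = simulate_survival(x, [0.0], lam, (1e6, 1e6 + 1), seed=1)
        assert events.mean() > 0.999
        assert times.mean() == pytest.approx(1 / lam, rel=0.05)

    def test_forced_censoring(self):
        eps = 1e-4
        times, events = simulate_survival(np.zeros((200, 1)), [0.0], 0.01, (eps, eps), seed=2)
        assert (events == 0).all()
        np.testing.assert_allclose(times, eps)

    def test_hazard_ratio_two(self):
        n = 5000
        x = np.concatenate([np.zeros((n, 1)), np.ones((n, 1))])
        times, events = simulate_survival(x, [np.log(2.0)], 0.02, (1e5, 1e5 + 1), seed=3)
        # all uncensored: exponential means differ by factor 2
        m0 = times[: n][events[:n] == 1].mean()
        m1 = times[n:][events[n:] == 1].mean()
        assert m0 / m1 == pytest.approx(2.0, rel=0.1)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            simulate_survival(np.zeros((5, 2)), [0.0], 0.01, (1, 2))

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            simulate_survival(np.full((5, 1), 0.5), [0.0], 0.01, (1, 2))

    def test_times_positive(self):
        times, events = simulate_survival(np.ones((100, 1)), [1.0], 0.1, (2.1, 49.2), seed=4)
        assert (times > 0).all()
        assert set(np.unique(events)) <= {0, 1}


class TestGenerateCohort:
    def test_default_mirrors_study_design(self):
        df = generate_cohort(CohortConfig(seed=0))
        assert len(df) == 56
        assert set(df["batch"]) <= {s.name for s in DEFAULT_SCANNERS}
        for f in ALL_FEATURES:
            assert f in df.columns
        assert {"total_mtv_cm3", "os_months", "event", "age", "sex", "m_status"} <= set(df.columns)

    def test_event_fraction_near_38_percent(self):
        cfg = dataclasses.replace(CohortConfig(), n_patients=20000, seed=5)
        df = generate_cohort(cfg)
        assert df["event"].mean() == pytest.approx(0.38, abs=0.04)

    def test_determinism(self):
        a = generate_cohort(CohortConfig(seed=9))
        b = generate_cohort(CohortConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(CohortConfig(seed=10))
        assert not a["os_months"].equals(c["os_months"])

    def test_planted_correlated_pair(self):
        from scipy.stats import spearmanr

        df = generate_cohort(dataclasses.replace(CohortConfig(), n_patients=500, seed=6))
        rho = spearmanr(df[PLANTED_CORR_PAIR[0]], df[PLANTED_CORR_PAIR[1]]).statistic
        assert rho > 0.95

    def test_cox_recovers_planted_hrs(self):
        from petsurv.survival import cox_fit

        cfg = dataclasses.replace(CohortConfig(), n_patients=2000, seed=3)
        df = generate_cohort(cfg)
        design = pd.DataFrame(
            {"mtv": df["truth_mtv_risk"].astype(float), "lze": df["truth_lze_risk"].astype(float)}
        )
        _, multi, _ = cox_fit(design, df["os_months"], df["event"])
        assert multi.hr("mtv") == pytest.approx(4.1, rel=0.15)
        assert multi.hr("lze") == pytest.approx(3.7, rel=0.15)

    def test_batch_location_shift_visible_then_harmonized(self):
        from petsurv.harmonization import apply_combat, fit_combat

        cfg = dataclasses.replace(
            CohortConfig(),
            n_patients=2000,
            batch_proportions=(0.5, 0.5),
            batch_labels=("a", "b"),
            batch_location_shift=(0.0, 2.0),
            batch_scale_factor=(1.0, 1.0),
            seed=11,
        )
        df = generate_cohort(cfg)
        feat = "GLRLM_SRE"  # nuisance feature, nominal N(0, 1)
        in_a = df["batch"] == "a"
        raw_gap = df.loc[~in_a, feat].mean() - df.loc[in_a, feat].mean()
        assert raw_gap == pytest.approx(2.0, abs=0.2)

        model = fit_combat(df[list(ALL_FEATURES)], df["batch"])
        harm = apply_combat(model, df[list(ALL_FEATURES)], df["batch"])
        gap = harm.loc[~in_a.values, feat].mean() - harm.loc[in_a.values, feat].mean()
        sd = harm.loc[in_a.values, feat].std()
        assert abs(gap) < 0.05 * sd

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            dataclasses.replace(CohortConfig(), lze_distribution=(0.0, 0.0))

    def test_null_cohort_logrank_null(self):
        # planted log HRs 0: indicator strata indistinguishable
        from petsurv.survival import logrank_test

        cfg = dataclasses.replace(
            CohortConfig(), n_patients=400, planted_log_hr_mtv=0.0, planted_log_hr_lze=0.0, seed=21
        )
        df = generate_cohort(cfg)
        _, p = logrank_test(df["truth_mtv_risk"], df["os_months"], df["event"])
        assert p > 0.01  # no planted signal

    def test_yaml_config(self, tmp_path):
        p = tmp_path / "cohort.yaml"
        p.write_text("n_patients: 30\nseed: 4\n")
        cfg = CohortConfig.from_yaml(p)
        assert cfg.n_patients == 30
        assert cfg.seed == 4
        assert len(generate_cohort(cfg)) == 30
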