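import numpy as np
import pytest

from petsurv.radiomics import (
    ALL_FEATURES,
    FAMILY_SIZES,
    LesionTooSmallError,
    discretize,
    extract_features,
    glcm_features,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    histogram_features,
    ngldm_features,
)

from .conftest import make_suv_volume, make_voi


class TestDiscretize:
    @pytest.mark.parametrize(
        "suv,level",
        [(0.0, 1), (0.49, 1), (0.5, 2), (31.49, 63), (31.5, 64), (31.99, 64), (40.0, 64), (-1.0, 1)],
    )
    def test_stated_binning_rule(self, suv, level):
        vol = make_suv_volume(np.full((2, 2, 2), suv))
        voi = discretize(vol, np.ones((2, 2, 2), bool))
        assert set(voi.in_mask_levels()) == {level}

    def test_constant_voi_single_level(self):
        vol = make_suv_volume(np.full((3, 3, 3), 4.2))
        voi = discretize(vol, np.ones((3, 3, 3), bool))
        assert len(np.unique(voi.in_mask_levels())) == 1

    def test_64_producible_levels(self):
        # dense SUV sweep over 0..40 must hit exactly 64 distinct levels
        suvs = np.linspace(0.0, 40.0, 4001).reshape((4001, 1, 1))
        vol = make_suv_volume(suvs, voxel_size_mm=(1, 1, 1))
        voi = discretize(vol, np.ones_like(suvs, bool))
        levels = np.unique(voi.in_mask_levels())
        assert len(levels) == 64
        assert levels.min() == 1 and levels.max() == 64

    def test_bin_geometry_invariant(self):
        vol = make_suv_volume(np.ones((2, 2, 2)))
        voi = discretize(vol, np.ones((2, 2, 2), bool))
        assert voi.bin_width_suv * voi.level_count == pytest.approx(32.0)

    def test_empty_mask_rejected(self):
        vol = make_suv_volume(np.ones((2, 2, 2)))
        with pytest.raises(ValueError, match="empty"):
            discretize(vol, np.zeros((2, 2, 2), bool))

    def test_non_suv_rejected(self):
        from petsurv.volume import PetVolume, Units

        vol = PetVolume(np.ones((2, 2, 2)), (1, 1, 1), Units.BQML)
        with pytest.raises(ValueError, match="SUV"):
            discretize(vol, np.ones((2, 2, 2), bool))


class TestGlszmExamples:
    def test_uniform_cube_single_zone(self):
        voi = make_voi(np.full((2, 2, 2), 3))
        f = glszm_features(voi)
        assert f["GLZLM_LZE"] == pytest.approx(64.0)
        assert f["GLZLM_SZE"] == pytest.approx(1.0 / 64.0)
        assert f["GLZLM_ZP"] == pytest.approx(1.0 / 8.0)

    def test_line_two_zones(self):
        voi = make_voi(np.array([1, 1, 2]).reshape(3, 1, 1))
        f = glszm_features(voi)
        assert f["GLZLM_LZE"] == pytest.approx((4 + 1) / 2)
        assert f["GLZLM_ZP"] == pytest.approx(2.0 / 3.0)

    def test_checkerboard_diagonal_zones(self):
        # 26-connectivity joins each diagonal pair -> 2 zones of size 2
        voi = make_voi(np.array([[1, 2], [2, 1]]).reshape(2, 2, 1))
        f = glszm_features(voi)
        assert f["GLZLM_LZE"] == pytest.approx(4.0)


class TestGlcmExamples:
    def test_constant_voi(self):
        f = glcm_features(make_voi(np.full((3, 3, 3), 5)))
        assert f["GLCM_Energy"] == pytest.approx(1.0)
        assert f["GLCM_Contrast"] == pytest.approx(0.0)
        assert f["GLCM_Dissimilarity"] == pytest.approx(0.0)
        assert f["GLCM_Entropy"] == pytest.approx(0.0)
        assert f["GLCM_Homogeneity"] == pytest.approx(1.0)
        assert f["GLCM_Correlation"] == pytest.approx(0.0)  # documented fallback

    def test_level_reversal_symmetry(self, rng):
        from .conftest import random_voi

        voi = random_voi(rng, max_level=8)
        rev = make_voi(np.where(voi.mask, 65 - voi.levels, 0), voi.mask)
        a, b = glcm_features(voi), glcm_features(rev)
        for name in ("GLCM_Energy", "GLCM_Entropy", "GLCM_Contrast", "GLCM_Dissimilarity", "GLCM_Homogeneity"):
            assert a[name] == pytest.approx(b[name], rel=1e-12)

    def test_isolated_voxels_rejected(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, 0] = True
        mask[4, 4, 4] = True
        with pytest.raises(ValueError, match="pair"):
            glcm_features(make_voi(np.ones((5, 5, 5), int), mask))


class TestGlrlmExamples:
    def test_single_run_per_direction_hook(self):
        voi = make_voi(np.full((1, 1, 4), 2))
        m = glrlm_matrix(voi, (0, 0, 1))
        n_runs = m.sum()
        assert n_runs == 1
        r = np.arange(1, m.shape[1] + 1)
        assert float((m * r**2).sum() / n_runs) == pytest.approx(16.0)  # LRE
        assert float((m / r**2).sum() / n_runs) == pytest.approx(1.0 / 16.0)  # SRE
        assert n_runs / voi.n_voxels == pytest.approx(1.0 / 4.0)  # RP along one direction

    def test_alternating_levels_all_short_runs(self):
        levels = np.array([1, 2, 1, 2, 1]).reshape(1, 1, 5)
        m = glrlm_matrix(make_voi(levels), (0, 0, 1))
        assert m.sum() == 5
        assert (m[:, 1:] == 0).all()  # every run has length 1

    def test_uniform_cube_features(self):
        # hand enumeration on a 2x2x2 cube: 3 axis directions give 4 runs of
        # length 2 each; 6 face diagonals give 2x(len 2) + 4x(len 1); 4 body
        # diagonals give 1x(len 2) + 6x(len 1) -> 28 runs of 2, 48 of 1
        f = glrlm_features(make_voi(np.full((2, 2, 2), 1)))
        assert f["GLRLM_LRE"] == pytest.approx((28 * 4 + 48) / 76)
        assert f["GLRLM_RP"] == pytest.approx(76 / (8 * 13))


class TestNgldmExamples:
    def test_constant_voi_contrast_zero(self):
        f = ngldm_features(make_voi(np.full((3, 3, 3), 4)))
        assert f["NGLDM_Contrast"] == pytest.approx(0.0)
        assert f["NGLDM_Busyness"] == pytest.approx(0.0)
        assert f["NGLDM_Coarseness"] == pytest.approx(1.0e6)  # capped guard

    def test_single_voxel_guard(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        with pytest.raises(ValueError, match="neighbour"):
            ngldm_features(make_voi(np.ones((3, 3, 3), int), mask))

    def test_two_voxel_voi_no_nan(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = mask[1, 1, 2] = True
        levels = np.ones((3, 3, 3), int)
        levels[1, 1, 2] = 3
        f = ngldm_features(make_voi(levels, mask))
        assert all(np.isfinite(v) for v in f.values())


class TestHistogramExamples:
    def test_constant_voi(self):
        f = histogram_features(make_voi(np.full((3, 3, 3), 7)))
        assert f["HISTO_EntropyLog2"] == pytest.approx(0.0)
        assert f["HISTO_Energy"] == pytest.approx(1.0)
        assert f["HISTO_Skewness"] == pytest.approx(0.0)  # 0/0 guard
        assert f["HISTO_Kurtosis"] == pytest.approx(0.0)

    def test_two_equally_likely_levels(self):
        levels = np.array([1, 1, 2, 2]).reshape(4, 1, 1)
        f = histogram_features(make_voi(levels))
        assert f["HISTO_EntropyLog2"] == pytest.approx(1.0)
        assert f["HISTO_Energy"] == pytest.approx(0.5)


class TestExtractFeatures:
    def test_exactly_41_named_features(self, sphere_volume):
        volume, masks, _ = sphere_volume
        fv = extract_features(volume, masks[0])
        assert list(fv.keys()) == list(ALL_FEATURES)
        assert len(fv) == 41
        assert sum(FAMILY_SIZES.values()) == 41
        assert FAMILY_SIZES == {
            "conventional": 5, "histogram": 5, "glcm": 6,
            "glrlm": 11, "ngldm": 3, "glzlm": 11,
        }
        assert all(np.isfinite(v) for v in fv.values())

    def test_63_voxel_mask_excluded(self, sphere_volume):
        volume, masks, _ = sphere_volume
        small = np.zeros(volume.shape, bool)
        idx = np.argwhere(masks[0])[:63]
        small[tuple(idx.T)] = True
        with pytest.raises(LesionTooSmallError, match="64"):
            extract_features(volume, small)

    def test_determinism(self, sphere_volume):
        volume, masks, _ = sphere_volume
        assert extract_features(volume, masks[0]) == extract_features(volume, masks[0])


class TestInvariants:
    def test_translation_invariance(self, rng):
        from .conftest import random_voi

        voi = random_voi(rng, max_shape=(4, 4, 4))
        big_levels = np.zeros((8, 8, 8), np.int64)
        big_mask = np.zeros((8, 8, 8), bool)
        sl = tuple(slice(2, 2 + s) for s in voi.levels.shape)
        big_levels[sl] = voi.levels
        big_mask[sl] = voi.mask
        shifted = make_voi(big_levels, big_mask)
        for fn in (glcm_features, glrlm_features, glszm_features, ngldm_features, histogram_features):
            a, b = fn(voi), fn(shifted)
            for k in a:
                assert a[k] == pytest.approx(b[k], rel=1e-12), k

    def test_zone_percentage_bounds(self, rng):
        from .conftest import random_voi

        for _ in range(10):
            f = glszm_features(random_voi(rng))
            assert 0.0 < f["GLZLM_ZP"] <= 1.0

    def test_lze_increases_with_texture_correlation_length(self):
        from scipy.stats import spearmanr

        from petsurv.synthetic import LesionSpec, PhantomConfig, ScannerProfile, generate_phantom

        lzes = []
        lengths = [2.0, 4.0, 8.0, 16.0]
        for corr in lengths:
            cfg = PhantomConfig(
                grid_shape=(26, 26, 26), background_suv=1.0,
                lesions=(LesionSpec((13, 13, 13), 11.0, 10.0, corr, 3.0),),
                scanner=ScannerProfile("s", 0.0, (2.0, 2.0, 2.0), 1.0, 0.0),
                seed=42,
            )
            volume, masks, _ = generate_phantom(cfg)
            lzes.append(extract_features(volume, masks[0])["GLZLM_LZE"])
        rho = spearmanr(lengths, lzes).statistic
        assert rho > 0
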