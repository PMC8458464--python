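import numpy as np
import pytest

from petsurv.radiomics.discretize import DiscretizedVoi
from petsurv.volume import PetVolume, Units


def make_voi(levels, mask=None) -> DiscretizedVoi:
    """Build a DiscretizedVoi directly from an integer level array."""
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    mask = np.asarray(mask, dtype=bool)
    lv = np.where(mask, levels, 0)
    return DiscretizedVoi(levels=lv, mask=mask, n_voxels=int(mask.sum()))


def random_voi(rng, max_shape=(6, 6, 6), max_level=8, mask_p=0.7) -> DiscretizedVoi:
    """Random small masked level grid; guaranteed >= 2 adjacent mask voxels."""
    while True:
        shape = tuple(int(rng.integers(2, s + 1)) for s in max_shape)
        mask = rng.random(shape) < mask_p
        if mask.sum() < 2:
            continue
        levels = rng.integers(1, max_level + 1, size=shape)
        voi = make_voi(levels, mask)
        # need at least one adjacent in-mask pair for GLCM
        idx = np.argwhere(mask)
        ok = False
        for a in idx:
            for b in idx:
                if not np.array_equal(a, b) and np.max(np.abs(a - b)) <= 1:
                    ok = True
                    break
            if ok:
                break
        if ok:
            return voi


def make_suv_volume(data, voxel_size_mm=(2.0, 2.0, 2.0), **kw) -> PetVolume:
    return PetVolume(
        data=np.asarray(data, dtype=float),
        voxel_size_mm=voxel_size_mm,
        units=Units.SUV,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sphere_volume():
    """Noise-free sphere phantom: background 1, lesion 10, r=10mm, voxel 2mm."""
    from petsurv.synthetic import LesionSpec, PhantomConfig, ScannerProfile, generate_phantom

    cfg = PhantomConfig(
        grid_shape=(24, 24, 24),
        background_suv=1.0,
        lesions=(LesionSpec((12, 12, 12), 10.0, 10.0, 4.0, 0.0),),
        scanner=ScannerProfile("ideal", 0.0, (2.0, 2.0, 2.0), 1.0, 0.0),
        seed=0,
    )
    return generate_phantom(cfg)
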