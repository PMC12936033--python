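import numpy as np
import pytest

from habicat import ImageVolume, PhantomConfig, RegionMask, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Nine small phantom subjects (3 per grade) shared across tests."""
    cfg = PhantomConfig(
        n_subjects_per_grade=3,
        grid_shape=(36, 36, 36),
        tumor_radius_range_mm=(5.0, 7.0),
        seed=7,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture
def random_region(rng):
    """A random intensity volume with a random blob-ish region inside."""

    def make(shape=(10, 10, 10), seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        values = r.normal(0, 30, size=shape)
        mask = np.zeros(shape, dtype=bool)
        lo = [s // 4 for s in shape]
        hi = [3 * s // 4 + 1 for s in shape]
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        # roughen the boundary
        drop = r.random(mask.shape) < 0.2
        mask &= ~drop
        if not mask.any():
            mask[shape[0] // 2, shape[1] // 2, shape[2] // 2] = True
        return ImageVolume(values), RegionMask(mask)

    return make
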