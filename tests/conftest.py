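import numpy as np
import pytest

from lipomics.phantom import VolumeWithMask, small_spec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sphere_volume():
    """Digital sphere of radius 15 voxels at 1 mm spacing, noisy interior."""
    n = 40
    z, y, x = np.mgrid[:n, :n, :n]
    c = (n - 1) / 2
    mask = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= 15**2
    g = np.random.default_rng(7)
    img = np.where(mask, 200.0 + g.normal(0, 20, mask.shape), 100.0)
    return VolumeWithMask(img, (1.0, 1.0, 1.0), mask)


@pytest.fixture(scope="session")
def small_case():
    """One deterministic phantom case from the scaled-down preset."""
    from lipomics.phantom import generate_case

    v, batch, label = generate_case(small_spec(seed=42), 0)
    return v


@pytest.fixture(scope="session")
def tiny_feature_table():
    """Feature table of a 16-case scaled-down phantom cohort (cached per session)."""
    from lipomics.features import extract_cohort_in_memory

    spec = small_spec(seed=9, n_cases=16)
    return extract_cohort_in_memory(spec)
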