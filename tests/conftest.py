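import numpy as np
import pytest

import tauscape as ts


@pytest.fixture(scope="session")
def toy_atlas():
    """Small 4-region layered atlas shared by read-only tests."""
    return ts.make_toy_atlas(shape=(32, 32, 32), pitch_um=8.3, n_regions=4)


@pytest.fixture(scope="session")
def planted_sample():
    """One 64^3 synthetic tau volume with 20 planted deposits (seed 7)."""
    atlas = ts.make_toy_atlas(shape=(64, 64, 64), n_regions=8)
    specs = ts.random_spot_specs(atlas, 20, amplitude=200.0, seed=7)
    volume, truth = ts.make_tau_volume(atlas, specs, seed=7)
    return atlas, specs, volume, truth


@pytest.fixture(scope="session")
def null_10k():
    """The 47-region, 3-sample, 10,000-replicate permutation null (seed 11)."""
    return ts.permutation_null(47, 3, n_perm=10_000, alpha=0.05, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
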