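"""Shared fixtures: one white-MC reference run feeds the whole suite."""

import numpy as np
import pytest

from sfdiml import (
    DiffusionForward,
    MCConfig,
    WhiteMCForward,
    build_forward_lut,
    generate_training_set,
    run_white_mc,
    train_regressor,
)

#: photon count of the shared reference simulation; large enough that MC
#: noise is well below the tolerances asserted downstream, small enough to
#: keep the suite fast.
SUITE_PHOTONS = 2_000_000


@pytest.fixture(scope="session")
def white_hist():
    return run_white_mc(MCConfig(n_photons=SUITE_PHOTONS, rng_seed=42))


@pytest.fixture(scope="session")
def mc_fwd(white_hist):
    return WhiteMCForward(white_hist)


@pytest.fixture(scope="session")
def diffusion_fwd():
    return DiffusionForward()


@pytest.fixture(scope="session")
def dense_lut(mc_fwd):
    return build_forward_lut(1000, 1000, mc_fwd)


@pytest.fixture(scope="session")
def low_lut(mc_fwd):
    return build_forward_lut(100, 100, mc_fwd)


@pytest.fixture(scope="session")
def train_set_1m(mc_fwd):
    return generate_training_set(1_000_000, 123, mc_fwd)


@pytest.fixture(scope="session")
def test_set_1m(mc_fwd):
    return generate_training_set(1_000_000, 456, mc_fwd)


@pytest.fixture(scope="session")
def rf_model(train_set_1m):
    return train_regressor(train_set_1m, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
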