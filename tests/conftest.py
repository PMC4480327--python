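import copy

import numpy as np
import pytest

from weeddyn import (
    SCENARIOS,
    calibrate_biomass_coeff,
    load_default_models,
    load_default_params,
)


@pytest.fixture(scope="session")
def models():
    return load_default_models()


@pytest.fixture()
def params():
    """Fresh uncalibrated default parameters (mutable per test)."""
    return load_default_params()


@pytest.fixture(scope="session")
def calibrated_coeff(models):
    p = load_default_params()
    return calibrate_biomass_coeff(p, models)


@pytest.fixture()
def calibrated_params(calibrated_coeff):
    p = load_default_params()
    p.biomass_coeff = calibrated_coeff
    return p


@pytest.fixture(scope="session")
def scenarios():
    return {k: copy.deepcopy(v) for k, v in SCENARIOS.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
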