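import numpy as np
import pytest

from lwlr_attrib import CoefficientFunction, SyntheticTruth, make_cell

CONST_BETA = (
    CoefficientFunction("constant", c0=0.25),
    CoefficientFunction("constant", c0=0.01),
    CoefficientFunction("constant", c0=-2e-4),
    CoefficientFunction("constant", c0=1e-3),
    CoefficientFunction("constant", c0=-2e-6),
)


@pytest.fixture
def const_truth():
    """Constant-coefficient, zero-noise generating truth (exact-model oracle)."""
    return SyntheticTruth(beta=CONST_BETA, noise_sigma=0.0, seed=12345)


@pytest.fixture
def exact_cell(const_truth):
    """120-month cell generated exactly by the fitting model, no noise."""
    return make_cell(const_truth, n_months=120, cell_id="exact")


@pytest.fixture
def noisy_cell():
    """240-month cell with constant coefficients and iid NDVI noise."""
    truth = SyntheticTruth(beta=CONST_BETA, noise_sigma=0.01, seed=777)
    return make_cell(truth, n_months=240, cell_id="noisy")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
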