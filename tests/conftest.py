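import numpy as np
import pytest

from singlesem import ChainWorld, SampleMoments, implied_covariance
from singlesem.fixtures import (
    saturated_pairs_model,
    saturated_pairs_truth,
    structured_pairs_model,
    structured_pairs_population,
    structured_pairs_truth,
)
from singlesem.model import ParamCell, SemModel


@pytest.fixture
def world():
    return ChainWorld()


@pytest.fixture
def structured_model():
    return structured_pairs_model()


@pytest.fixture
def structured_truth():
    return structured_pairs_truth()


@pytest.fixture
def structured_pop():
    return structured_pairs_population(N=500)


@pytest.fixture
def saturated_model():
    return saturated_pairs_model()


@pytest.fixture
def saturated_truth():
    return saturated_pairs_truth()


def downstream_model(err5: float) -> SemModel:
    """One latent with a scaling indicator y5 (fixed error variance ``err5``),
    a second indicator y6, and two downstream single-indicator latents.

    Because the focal latent causes several other latents, its scaling
    indicator's error variance is identified even though fixed — the setting
    where a wrong assertion produces a nonzero modification index.
    """
    m = SemModel(["eta3", "eta4", "eta5"], ["y5", "y6", "y7", "y8"])
    m.set_loading("y5", "eta3", ParamCell("fixed", 1.0))
    m.set_loading("y6", "eta3", ParamCell("free", None))
    m.set_loading("y7", "eta4", ParamCell("fixed", 1.0))
    m.set_loading("y8", "eta5", ParamCell("fixed", 1.0))
    m.set_effect("eta3", "eta4", ParamCell("free", None))
    m.set_effect("eta3", "eta5", ParamCell("free", None))
    m.set_psi("eta3", "eta3", ParamCell("free", None))
    m.set_psi("eta4", "eta4", ParamCell("free", None))
    m.set_psi("eta5", "eta5", ParamCell("free", None))
    m.set_theta("y5", "y5", ParamCell("fixed", err5))
    m.set_theta("y6", "y6", ParamCell("free", None))
    m.set_theta("y7", "y7", ParamCell("fixed", 0.3))
    m.set_theta("y8", "y8", ParamCell("fixed", 0.35))
    m.validate(strict=False)
    return m


DOWNSTREAM_TRUTH = {
    "load:y6~eta3": 0.8,
    "effect:eta3->eta4": 0.5,
    "effect:eta3->eta5": 0.6,
    "psi:eta3,eta3": 1.5,
    "psi:eta4,eta4": 0.4,
    "psi:eta5,eta5": 0.5,
    "theta:y6,y6": 0.5,
}

# Error accumulations for a chain behind y5 with disturbance variances
# errC = 0.2 and err5 = 0.5: the common-cause (B) identity accumulates both,
# the downstream (C) identity only the direct measurement disturbance.
DOWNSTREAM_ERR5_TRUE = 0.7  # identity-B accumulation (errC + err5)
DOWNSTREAM_ERR5_WRONG = 0.5  # identity-C accumulation: too small


@pytest.fixture
def downstream_population():
    truth_model = downstream_model(DOWNSTREAM_ERR5_TRUE)
    Sigma = implied_covariance(truth_model, DOWNSTREAM_TRUTH).Sigma
    return SampleMoments(Sigma, 10000, list(truth_model.indicator_names))
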