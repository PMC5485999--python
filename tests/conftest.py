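import numpy as np
import pytest
from hypothesis import settings

from repairkinetics import (
    IrradiationProtocol,
    ModelParameters,
    PathwayRates,
    SolverConfig,
    pooled_sarcoma_parameters,
    study_protocol,
    table1_fixture,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pooled_params() -> ModelParameters:
    """Pooled-sarcoma one-pathway parameter set."""
    return pooled_sarcoma_parameters()


@pytest.fixture(scope="session")
def protocol() -> IrradiationProtocol:
    """One 6 Gy fraction over a 2 min rectangular pulse."""
    return study_protocol()


@pytest.fixture(scope="session")
def fixture_series():
    """Published difference-of-medians time-course."""
    return table1_fixture()


@pytest.fixture(scope="session")
def coarse_solver() -> SolverConfig:
    return SolverConfig(step=0.2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170601)


def one_pathway(kcleav=1.0, k0=0.4, k1=0.03, k2=0.01, tr=0.0, bn=0.0):
    return ModelParameters(kcleav=kcleav, fast=PathwayRates(k0, k1, k2, tr), bn=bn)
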