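import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

import phytorsm as pr


@pytest.fixture(scope="session")
def factors():
    return pr.datasets.extraction_factors()


@pytest.fixture(scope="session")
def design(factors):
    return pr.build_ccrd(factors, {1: 4, 2: 2}, seed=0)


@pytest.fixture(scope="session")
def tpc_data():
    """The published 20-run sheet packaged for fitting."""
    return pr.datasets.tpc_response_data()


@pytest.fixture(scope="session")
def printed_model(factors):
    """The published coded-unit TPC equation as a predict-able model."""
    return pr.model_from_coefficients(
        pr.datasets.fitted_tpc_coefficients(), 3, tuple(factors)
    )


@pytest.fixture(scope="session")
def surface_truth():
    return pr.default_surface_truth()
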