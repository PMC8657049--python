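import warnings

import pytest

from opetk.fixtures import make_fixture_bundle
from opetk.pipeline import run_from_fixtures


@pytest.fixture(scope="session")
def bundle():
    """Uncalibrated fixture bundle shared across the suite."""
    return make_fixture_bundle(seed=7)


@pytest.fixture(scope="session")
def calibrated_bundle():
    return make_fixture_bundle(seed=7, calibrate=True)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full calibrated run (n = 1000 per population) shared by tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # extreme-tail estimator warnings at n=1000
        return run_from_fixtures(seed=7, n=1000, calibrate=True)
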