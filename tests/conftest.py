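import numpy as np
import pytest

from prscap import coverage, synthgeno


@pytest.fixture(scope="session")
def calibrated_panel():
    """The default calibrated panel shared by the slower analyses."""
    return synthgeno.default_panel(seed=7)


@pytest.fixture(scope="session")
def calibrated_capture(calibrated_panel):
    return coverage.build_capture_table(calibrated_panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
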