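import numpy as np
import pytest

from fmeaplus import default_taxonomy
from fmeaplus.fixtures import (
    detectability_matrix,
    factor_matrix,
    occurrence_matrix,
    severity_matrix,
)


@pytest.fixture(scope="session")
def factor_fm():
    return factor_matrix()


@pytest.fixture(scope="session")
def subfactor_fms():
    return {
        "occurrence": occurrence_matrix(),
        "severity": severity_matrix(),
        "detectability": detectability_matrix(),
    }


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
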