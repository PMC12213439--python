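import numpy as np
import pytest

from oscillometry import (
    ComplianceParams,
    CuffProtocol,
    OscillogramKind,
)
from oscillometry.fitting import synthesize_case


@pytest.fixture(scope="session")
def std_params() -> ComplianceParams:
    """Typical brachial compliance widths from height-oscillogram fitting."""
    return ComplianceParams(amplitude=1.0, width_neg=11.0, width_pos=14.0)


@pytest.fixture(scope="session")
def default_protocol() -> CuffProtocol:
    return CuffProtocol()


@pytest.fixture(scope="session")
def elastic_case():
    """Noiseless elastic recording (250 Hz, 3 mmHg/s) with measured oscillograms."""
    return synthesize_case(b=11.0, c=14.0, Ps=120.0, Pd=80.0, seed=11)


@pytest.fixture(scope="session")
def elastic_measured_height(elastic_case):
    return elastic_case.measured[OscillogramKind.HEIGHT]


def random_width_draws(n, seed, lo=2.0, hi=40.0):
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=(n, 2))
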