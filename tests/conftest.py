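import numpy as np
import pytest

from spatialssa import RateParameters


@pytest.fixture(scope="session")
def gene_params():
    """Rates of the tight-binding gene-expression scenarios (omega = 1)."""
    return RateParameters(
        kf=5000.0, kb=100.0, kp=50.0, kd=0.001, delta=0.2, omega=1.0
    )


@pytest.fixture(scope="session")
def grid50():
    return np.linspace(0.0, 50.0, 501)
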