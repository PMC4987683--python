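import numpy as np
import pytest

from ebclock.kinetics import ImpulseParams


@pytest.fixture
def canonical_params() -> ImpulseParams:
    """A typical baseline-experiment impulse curve."""
    return ImpulseParams(A=3000.0, beta1=0.5, beta2=0.3, t1=85.0, t2=100.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
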