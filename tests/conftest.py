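import numpy as np
import pytest

from sinres.mackey_glass import MGConfig, center, generate_mg


@pytest.fixture(scope="session")
def mg5000():
    """Centered default Mackey-Glass series, 5000 samples."""
    return center(generate_mg(MGConfig(length=5000)))


@pytest.fixture(scope="session")
def mg2100():
    """Centered teacher series long enough for training plus horizon."""
    return center(generate_mg(MGConfig(length=2100)))


@pytest.fixture(scope="session")
def logistic_series():
    """Fully chaotic logistic map x -> 4x(1-x); lambda_max = ln 2 exactly."""
    x = 0.3
    out = np.empty(5000)
    for i in range(5000):
        x = 4.0 * x * (1.0 - x)
        out[i] = x
    return out
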