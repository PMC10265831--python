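import numpy as np
import pytest

from glymkin.io_core import TimeSignalCurve
from glymkin.synth import default_times, gamma_variate_input, generate_inner_from_outer


@pytest.fixture
def times40():
    """The standard 40-frame grid over 6 h."""
    return default_times()


@pytest.fixture
def gamma_curve(times40):
    """A typical delayed-rise/peak/decay input curve."""
    return gamma_variate_input(20.0, 30.0, 2.0, 40.0, times40, label="outer")


@pytest.fixture
def exchange_pair(times40, gamma_curve):
    """Noise-free (outer, inner, k1, k2) quadruple."""
    k1, k2 = 0.02, 0.012
    inner = generate_inner_from_outer(gamma_curve, k1, k2)
    return gamma_curve, inner, k1, k2


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_curve(values, times=None, **kwargs):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(values.size, dtype=float)
    return TimeSignalCurve(times, values, **kwargs)
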