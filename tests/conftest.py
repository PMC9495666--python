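import numpy as np
import pytest

from adiagait.signals import UniformSignal


def make_sine(amplitude=0.02, freq=1.0, rate=1200.0, duration=10.0, phase=0.0):
    """Pure sine Q and its analytic derivative P."""
    t = np.arange(int(round(duration * rate))) / rate
    q = UniformSignal(amplitude * np.sin(2 * np.pi * freq * t + phase), rate)
    p = UniformSignal(
        2 * np.pi * freq * amplitude * np.cos(2 * np.pi * freq * t + phase), rate
    )
    return q, p


@pytest.fixture
def sine_qp():
    return make_sine()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
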