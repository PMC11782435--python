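import numpy as np
import pytest
from hypothesis import settings

from osteoimpact.synthetic_data import GeneratorConfig, generate_database

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

SAMPLING_RATE = 51.2e3


def two_gaussian_trace(
    centers_ms=(1.0, 2.5),
    amplitudes=(150.0, 75.0),
    widths_ms=(0.15, 0.15),
    duration_ms=20.0,
    sampling_rate=SAMPLING_RATE,
):
    """Construct a two-pulse force trace directly from the pulse equation.

    Independent of the package's generator so it can serve as an oracle.
    """
    n = int(round(duration_ms * 1e-3 * sampling_rate))
    t_s = np.arange(n) / sampling_rate
    t_ms = t_s * 1e3
    force = np.zeros(n)
    for c, a, w in zip(centers_ms, amplitudes, widths_ms):
        force += a * np.exp(-((t_ms - c) ** 2) / (2 * w**2))
    return t_s, force


@pytest.fixture(scope="session")
def small_experiment():
    """Two-plate seeded experiment shared by tests that only read it."""
    return generate_database(GeneratorConfig(seed=11, n_plates=2))


@pytest.fixture
def small_config():
    return GeneratorConfig(seed=11, n_plates=2)
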