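import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from sonobubble.agents import AGENTS, MOUSE_BLOOD  # noqa: E402
from sonobubble.pulses import synthesize_tone_burst  # noqa: E402


@pytest.fixture(scope="session")
def medium():
    return MOUSE_BLOOD


@pytest.fixture(scope="session")
def agents():
    return AGENTS


@pytest.fixture(scope="session")
def treatment_pulse():
    """1.8 MHz, 20 us, 0.268 MPa Tukey(0.25) burst — the in vivo treatment
    exposure synthesized from its stated parameters."""
    return synthesize_tone_burst(1.8e6, 20e-6, 0.268e6, "tukey(0.25)", 100e6,
                                 label="treatment")


@pytest.fixture(scope="session")
def zero_pulse():
    """Same grid as the treatment pulse but zero amplitude."""
    return synthesize_tone_burst(1.8e6, 20e-6, 0.0, "rectangular", 100e6,
                                 label="silence")
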