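import numpy as np
import pytest

from adamsync import (
    AdaptParams,
    AgentSpec,
    NoiseParams,
    gen_isochronous,
)


@pytest.fixture
def metronome_500():
    """A 500 ms isochronous metronome with 50 events."""
    return gen_isochronous(500.0, 50)


@pytest.fixture
def phase_agent():
    """Noise-free phase-only agent with alpha = 0.5, base period 500 ms."""
    return AgentSpec(adapt=AdaptParams(alpha=0.5), base_period_ms=500.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
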