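import numpy as np
import pytest

from stepcal import ObjectiveCurve, SubjectiveCurve, VirtualParticipant


@pytest.fixture
def canonical_participant() -> VirtualParticipant:
    """The worked-example observer: threshold 25, rise 20, visibility (25, 10)."""
    return VirtualParticipant(
        objective=ObjectiveCurve(theta1=25.0, theta2=20.0),
        subjective=SubjectiveCurve(theta=25.0, sigma=10.0),
        id="canonical",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
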