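import math

import pytest
from hypothesis import HealthCheck, settings

from stenoflow import ForceField, caption_defaults

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def caption_config():
    """The anchor parameter set of the reproduced figures."""
    return caption_defaults()


@pytest.fixture
def caption_forces():
    return ForceField(magnetization=2.0, gravity=0.3, inclination=math.pi / 6)


@pytest.fixture
def no_forces():
    return ForceField(magnetization=0.0, gravity=0.0, inclination=0.0)
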