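import pytest
from hypothesis import HealthCheck, settings

from ankledyn import build_reference_subject

settings.register_profile(
    "repeatable",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def subject():
    """The shipped reference subject (73 kg, 1.70 m, 10-kg waist load)."""
    return build_reference_subject()
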