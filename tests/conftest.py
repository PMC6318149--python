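import pytest
from hypothesis import HealthCheck, settings

from cogtaskgen.banks import ContentBank
from cogtaskgen.models import load_model_registry

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return load_model_registry()


@pytest.fixture(scope="session")
def bank():
    return ContentBank.default()
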