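import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def norms():
    from camnorms import builtin_cameroon_norms

    return builtin_cameroon_norms()


@pytest.fixture(scope="session")
def default_spec():
    from camnorms import default_cameroon_spec

    return default_cameroon_spec()
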