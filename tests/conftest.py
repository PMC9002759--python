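import pytest
from hypothesis import HealthCheck, settings

from awbox import fixtures as fx
from awbox.model import BindingSiteModel

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def records():
    return fx.load_fixtures()


@pytest.fixture(scope="session")
def tested_canonical(records):
    return fx.select(records, tested_only=True, canonical_only=True)


@pytest.fixture(scope="session")
def bound_records(tested_canonical):
    return fx.select(tested_canonical, label_filter="bound")


@pytest.fixture(scope="session")
def fitted(records):
    return BindingSiteModel.from_records(records).fit()
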