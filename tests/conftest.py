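import pytest
from hypothesis import settings

import rsreval as rv

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def result_2009():
    return rv.evaluate_fixture(2009)


@pytest.fixture(scope="session")
def result_2019():
    return rv.evaluate_fixture(2019)


@pytest.fixture(scope="session")
def summary():
    return rv.paper_summary()
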