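import pytest

from mrsdat import load_ffq_schema, load_recommendations


@pytest.fixture(scope="session")
def recs():
    return load_recommendations()


@pytest.fixture(scope="session")
def schema():
    return load_ffq_schema()
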