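import pytest

from footcea import peru_2012


@pytest.fixture(scope="session")
def peru():
    """The bundled Peru-2012 scenario (session-scoped; ParameterSet is frozen)."""
    return peru_2012()
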