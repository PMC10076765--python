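import pytest

from eqrbot.fixtures import frida_scenario, run_pipeline


@pytest.fixture(scope="session")
def frida():
    return frida_scenario()


@pytest.fixture(scope="session")
def frida_result(frida):
    """The Frida scenario pushed through the full pipeline once."""
    return run_pipeline(frida)


@pytest.fixture(scope="session")
def frida_kb(frida_result):
    return frida_result.kb


@pytest.fixture(scope="session")
def frida_repo(frida_result):
    return frida_result.repository
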