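import pytest

from crnemu import netlib


@pytest.fixture(scope="session")
def am():
    return netlib.builtin("am").network


@pytest.fixture(scope="session")
def mi_fixture():
    return netlib.builtin("mi")


@pytest.fixture(scope="session")
def mi_net(mi_fixture):
    return mi_fixture.compiled


@pytest.fixture(scope="session")
def mi_to_am():
    return netlib.builtin("mi_to_am_morphism").morphism


@pytest.fixture(scope="session")
def fig6():
    return {name: netlib.builtin(name).morphism
            for name in ("fig6a", "fig6b", "fig6d", "fig6f")}
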