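import pytest

from depcrsim.design import default_design, make_pool


@pytest.fixture(scope="session")
def design():
    """The canonical 10-template x 64-primer design space."""
    return default_design()


@pytest.fixture(scope="session")
def space(design):
    return design.space


@pytest.fixture(scope="session")
def pools():
    return {name: make_pool(name) for name in
            ["A", "B", "C", "D", "E", "1", "9", "10", "27", "64"]}
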