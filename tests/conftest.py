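import pytest

from ldexact import enumerate_states


@pytest.fixture(scope="session")
def spaces():
    """Session-cached state spaces keyed by ne."""
    cache = {}

    def get(ne):
        if ne not in cache:
            cache[ne] = enumerate_states(ne)
        return cache[ne]

    return get


@pytest.fixture(scope="session")
def space2(spaces):
    return spaces(2)


@pytest.fixture(scope="session")
def space3(spaces):
    return spaces(3)


@pytest.fixture(scope="session")
def space5(spaces):
    return spaces(5)
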