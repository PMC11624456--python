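import pytest

from popchar.model import Characteristic, MentionSpan
from popchar.resources import default_engine


@pytest.fixture(scope="session")
def engine():
    return default_engine()


@pytest.fixture(scope="session")
def lexicons(engine):
    return engine[0]


@pytest.fixture(scope="session")
def rules(engine):
    return engine[1]


@pytest.fixture(scope="session")
def normalizer(engine):
    return engine[2]


@pytest.fixture(scope="session")
def mk_mention():
    """Factory for free-standing mentions (offsets relative to surface)."""

    def make(kind: Characteristic, surface: str, low=None, high=None):
        return MentionSpan(kind, surface, 0, len(surface), "test", low, high)

    return make
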