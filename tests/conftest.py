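import pytest

from linkcom import Network
from linkcom import synthetic as syn


@pytest.fixture
def triangle() -> Network:
    return Network.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3() -> Network:
    """Path a-b-c-d: three links, two interior joints."""
    return Network.from_edges([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture(scope="session")
def five_cliques():
    """Union of the five benchmark cliques overlapping at nodes 1,7,12,16."""
    return syn.five_clique_union()


@pytest.fixture(scope="session")
def karate() -> Network:
    return syn.karate_club()
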