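import pytest

from spreadnet import Network


@pytest.fixture
def path2():
    return Network.from_edges([("A", "B")])


@pytest.fixture
def path3():
    return Network.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def triangle():
    return Network.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star4():
    """Hub 'c' with three leaves."""
    return Network.from_edges([("c", "l1"), ("c", "l2"), ("c", "l3")])


@pytest.fixture
def isolated():
    return Network.from_edges([], nodes=["A"])
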