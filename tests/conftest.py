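import pytest

from exhaustnet.diffprize import PrizeMap
from exhaustnet.interactome import Interaction, assemble, attach_dummy, compute_costs
from exhaustnet.pcsf import PCSFConfig


@pytest.fixture
def default_cfg():
    return PCSFConfig()


@pytest.fixture
def star_graph():
    """a -> {b, c, d, e}: one hub with 4 out-edges (each cost 0.75)."""
    return compute_costs(
        assemble([Interaction("a", x) for x in ("b", "c", "d", "e")])
    )


@pytest.fixture
def chain_graph():
    """r -> a -> b chain; every edge forced (cost 0)... costs depend on outdegree."""
    return compute_costs(
        assemble([Interaction("r", "a"), Interaction("a", "b")])
    )


@pytest.fixture
def two_edge_graph():
    """a -> b, a -> c: each out-edge of a has cost 0.5."""
    return compute_costs(
        assemble([Interaction("a", "b"), Interaction("a", "c")])
    )


@pytest.fixture
def simple_prizes():
    return PrizeMap({"a": 2.0, "b": 1.0})


def make_augmented(g, prizes, omega=1.0, policy="prized"):
    return attach_dummy(g, policy=policy, omega=omega, prizes=prizes)
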