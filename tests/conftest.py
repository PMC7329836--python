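import warnings

import numpy as np
import pytest

from netpas import (
    FixtureSpec,
    GeneSet,
    GeneSetCollection,
    MS02Config,
    Network,
    make_fixture,
)


@pytest.fixture
def triangle_net() -> Network:
    return Network.from_edge_labels([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def two_disjoint_edges() -> Network:
    return Network.from_edge_labels([("a", "b"), ("c", "d")])


@pytest.fixture
def star_net() -> Network:
    return Network.from_edge_labels([("hub", f"leaf{i}") for i in range(4)])


@pytest.fixture(scope="session")
def small_fixture():
    """500-node preferential-attachment network with 6 random gene sets."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_fixture(
            FixtureSpec(n_nodes=500, attachment=3, n_sets=6, set_size=(20, 60), seed=13)
        )


@pytest.fixture(scope="session")
def planted_fixture():
    """Fixture with a strong planted surplus between set01 and set02 and
    planted within-set edges inside set01."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_fixture(
            FixtureSpec(
                n_nodes=500,
                attachment=3,
                n_sets=6,
                set_size=(25, 45),
                planted=(("set01", "set02", 60), ("set01", "set01", 40)),
                seed=21,
            )
        )


@pytest.fixture
def quick_config() -> MS02Config:
    return MS02Config(seed=1234, n_models=150)
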