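import numpy as np
import pytest

import asekit as ak
from asekit.trees import TaxonAges, TimeTree, read_tree


def dated_tree(newick: str, tip_ages: dict, root_extra: float = 2.0) -> TimeTree:
    """Small hand-dated tree: tips at the given ages, internal nodes spread
    evenly above their oldest child, root raised by ``root_extra``."""
    topo = read_tree(newick)
    ages = TaxonAges(dict(tip_ages), dict(tip_ages))
    tt = TimeTree.from_ages(topo, ages)
    # push internal nodes up so every branch is positive
    for node in tt.tree.postorder_node_iter():
        if not node.is_leaf():
            node.age = max(c.age for c in node.child_nodes()) + root_extra
    tt.sync_edge_lengths()
    return tt


@pytest.fixture(scope="session")
def five_tip_tree() -> TimeTree:
    return dated_tree(
        "(((A,B),C),(D,E));",
        {"A": 0.0, "B": 1.0, "C": 0.5, "D": 0.0, "E": 2.0},
        root_extra=1.5,
    )


@pytest.fixture(scope="session")
def four_tip_tree() -> TimeTree:
    return dated_tree(
        "((A,B),(C,D));", {"A": 0.0, "B": 0.5, "C": 1.0, "D": 0.0}, root_extra=2.0
    )


@pytest.fixture(scope="session")
def fixture_data():
    """The canned 12-tip feather-like data set."""
    return ak.fixture_dataset(seed=11)


@pytest.fixture(scope="session")
def fixture_tree(fixture_data):
    return ak.timescale_equal(fixture_data["tree"].tree, fixture_data["ages"], 1.0)
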