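import hypothesis
import numpy as np
import pytest

import edam

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def caterpillar():
    """((A:1,B:1):1,C:2); — the worked 3-tip example used throughout."""
    return edam.read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def isolated_genus_tree():
    """Ultrametric 5-tip tree whose pendant branches attach at ages
    (0.1, 0.1, 0.1, 0.1, 4.0); genus E sits on an isolated long branch."""
    return edam.read_tree(
        "((A:0.1,B:0.1):3.9,(C:0.1,D:0.1):3.9,E:4.0);"
    )


@pytest.fixture(scope="session")
def small_study():
    """One deterministic synthetic study shared by read-only tests."""
    return edam.simulate_study(
        edam.SimulationConfig(n_species=30, n_genera=12, n_cells=200, seed=42)
    )


def fair_proportion_oracle(tree, include_root=False):
    """Brute-force ED: distribute each branch's length equally among its
    descendant tips by explicit enumeration.  Independent of the package's
    single-pass implementation."""
    ed = {leaf.taxon.label: 0.0 for leaf in tree.leaf_node_iter()}
    for node in tree.preorder_node_iter():
        if node.parent_node is None and not include_root:
            continue
        length = node.edge.length or 0.0
        tips = [l.taxon.label for l in node.leaf_iter()]
        for t in tips:
            ed[t] += length / len(tips)
    return ed
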