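import numpy as np
import pytest

from phylocarto.tree import AnnotatedTree, Node


def build_tree(spec, mrsd=None) -> AnnotatedTree:
    """Build an AnnotatedTree from a nested spec tuple.

    Each node spec is (label, branch_length, lat, lon, children) where
    children is a list of node specs (empty for tips) and branch_length is
    None for the root.
    """
    nodes: dict[int, Node] = {}

    def add(s, parent):
        label, bl, lat, lon, children = s
        nid = len(nodes)
        nodes[nid] = Node(
            id=nid, parent=parent, branch_length=bl, taxon_label=label,
            latitude=lat, longitude=lon,
        )
        if parent is not None:
            nodes[parent].children.append(nid)
        for c in children:
            add(c, nid)

    add(spec, None)
    return AnnotatedTree(nodes, 0, most_recent_sampling_date=mrsd)


@pytest.fixture
def two_tip_tree():
    """Root at the origin, two tips 3 years later at distinct locations."""
    return build_tree(
        (None, None, 0.0, 0.0, [
            ("A", 3.0, 1.0, 1.0, []),
            ("B", 3.0, -1.0, 2.0, []),
        ]),
        mrsd=2020.0,
    )


@pytest.fixture
def balanced_four_tip_tree():
    return build_tree(
        (None, None, 0.0, 0.0, [
            (None, 1.0, 1.0, 0.0, [
                ("A", 1.0, 2.0, 0.0, []),
                ("B", 1.0, 2.0, 1.0, []),
            ]),
            (None, 1.0, -1.0, 0.0, [
                ("C", 1.0, -2.0, 0.0, []),
                ("D", 1.0, -2.0, -1.0, []),
            ]),
        ]),
        mrsd=2010.0,
    )


@pytest.fixture
def caterpillar_five_tip_tree():
    """Pectinate tree: the spine has 4 edges (maximum depth 4)."""
    return build_tree(
        (None, None, 0.0, 0.0, [
            (None, 1.0, 1.0, 1.0, [
                (None, 1.0, 2.0, 2.0, [
                    (None, 1.0, 3.0, 3.0, [
                        ("D", 1.0, 4.0, 4.0, []),
                        ("E", 1.0, 4.0, 5.0, []),
                    ]),
                    ("C", 1.0, 3.0, 4.0, []),
                ]),
                ("B", 1.0, 2.0, 3.0, []),
            ]),
            ("A", 1.0, 1.0, 2.0, []),
        ])
    )


def random_annotated_tree(n_tips, seed, sigma=1.0, states=("A", "B"), scale=1.0):
    """Seeded simulated tree with coordinates and a discrete trait."""
    from phylocarto.simulate import SimulationConfig, simulate_dataset

    config = SimulationConfig(
        n_tips=n_tips, seed=seed, sigma=sigma, states=list(states), true_scale=scale
    )
    return simulate_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
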