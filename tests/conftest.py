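import numpy as np
import pytest

from threetaxon.io import Alignment
from threetaxon.trees import Node, Tree
from threetaxon.parsimony import _attachable_edges, _insert_at_edge


def random_tree(labels, rng, rooted=False):
    """Uniform-ish random binary topology by random sequential insertion."""
    labels = list(labels)
    root = Node()
    for l in labels[:3]:
        root.add(Node(l))
    t = Tree(root, rooted=False)
    for lab in labels[3:]:
        edges = _attachable_edges(t)
        _insert_at_edge(t, edges[int(rng.integers(len(edges)))], Node(lab))
    if rooted:
        t = t.root_with_outgroup(labels[0])
    t.rooted = rooted
    return t


def random_alignment(labels, ncols, rng, symbols="ACGT"):
    syms = np.array(list(symbols))
    data = syms[rng.integers(0, len(syms), size=(len(labels), ncols))]
    return Alignment(list(labels), data)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toys():
    from threetaxon.simulate import fixture_toys

    return fixture_toys()
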