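import numpy as np
import pytest

from fernwgd.simulate import fern_species_tree
from fernwgd.trees import ladderize


@pytest.fixture(scope="session")
def fern_tree():
    """The ladderized 7-taxon fern fixture used across tests."""
    return ladderize(fern_species_tree())


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_rooted_tree(labels, rng, with_lengths=True):
    """A uniformly random rooted binary tree as a Newick string."""
    from fernwgd.trees import Node, Tree

    nodes = [Node(label=lab) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = Node()
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    tree = Tree(nodes[0])
    if with_lengths:
        for node in tree.preorder():
            if node is not tree.root:
                node.length = float(np.round(rng.uniform(0.1, 5.0), 6))
    return tree.to_newick()


def enumerate_topologies(labels):
    """All rooted binary topologies on the given leaf labels (as nested
    tuples), by inserting each successive leaf on every edge."""
    def insert_everywhere(tree, leaf):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            left, right = tree
            for sub in insert_everywhere(left, leaf):
                yield (sub, right)
            for sub in insert_everywhere(right, leaf):
                yield (left, sub)

    trees = [labels[0]]
    for leaf in labels[1:]:
        trees = [t for base in trees for t in insert_everywhere(base, leaf)]
    return trees


def topology_to_newick(tree):
    if isinstance(tree, tuple):
        return "(" + ",".join(topology_to_newick(c) for c in tree) + ")"
    return str(tree)
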