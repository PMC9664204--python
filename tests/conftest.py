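import random

import pytest

from wgdkit import fixtures
from wgdkit.io_formats.trees import Tree, TreeNode


@pytest.fixture(scope="session")
def species_tree():
    return fixtures.species_tree()


@pytest.fixture(scope="session")
def event_history(species_tree):
    return fixtures.event_history(tree=species_tree)


@pytest.fixture(scope="session")
def presence_matrix():
    return fixtures.presence_matrix()


def random_binary_tree(n_leaves: int, rng: random.Random) -> Tree:
    """Random rooted binary tree with leaves L0..L{n-1} via random merges."""
    nodes = [TreeNode(f"L{i}") for i in range(n_leaves)]
    counter = 0
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        parent = TreeNode(f"N{counter}")
        counter += 1
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    return Tree(nodes[0])
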