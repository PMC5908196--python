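import numpy as np
import pytest

from lgtrecon.trees import Node, Tree, parse_newick


def random_binary_tree(rng, labels, kind="gene"):
    """Uniform-ish random rooted binary tree over the given leaf labels."""
    nodes = [Node(label=lb) for lb in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        p = Node()
        p.add_child(a)
        p.add_child(b)
        nodes.append(p)
    return Tree(nodes[0], kind=kind)


def random_species_tree(rng, n):
    return random_binary_tree(rng, [f"sp{i}" for i in range(n)], kind="species")


def random_gene_tree(rng, species_labels, n_leaves):
    picks = [
        species_labels[int(rng.integers(len(species_labels)))]
        for _ in range(n_leaves)
    ]
    return random_binary_tree(
        rng, [f"{s}|g{i}" for i, s in enumerate(picks)], kind="gene"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def species_abc():
    return parse_newick("((A,B),C);", kind="species")


@pytest.fixture
def gene_acb():
    # topology discordant with ((A,B),C): C groups with A
    return parse_newick("((A|a1,C|c1),B|b1);", kind="gene")
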