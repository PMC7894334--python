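"""Shared fixtures and random-structure generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from linfam.io import CladeMap
from linfam.trees import GeneTree, Node


def random_topology(rng: np.random.Generator, leaf_names: list[str]) -> Node:
    """Random rooted binary topology by sequential random joins."""
    nodes = [Node(name=name, length=1.0) for name in leaf_names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = Node(length=1.0)
        parent.add_child(left)
        parent.add_child(right)
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def random_gene_tree(
    rng: np.random.Generator,
    n_leaves: int,
    species_pool: dict[str, str],
    support_choices=(40, 55, 60, 75, 90, 100),
    support_absent_frac: float = 0.0,
) -> GeneTree:
    """Random gene tree with species drawn from ``species_pool`` (sp -> clade)."""
    species = list(species_pool)
    names = []
    for i in range(n_leaves):
        sp = species[int(rng.integers(len(species)))]
        names.append(f"g{i}_{sp}")
    root = random_topology(rng, names)
    tree = GeneTree(root, {n: n.split("_", 1)[1] for n in names})
    for node in tree.preorder():
        if node.is_leaf or node is tree.root:
            continue
        if support_absent_frac and rng.random() < support_absent_frac:
            node.support = None
        else:
            node.support = int(rng.choice(support_choices))
    return tree


@pytest.fixture
def abd_clade_map() -> CladeMap:
    return CladeMap(
        {
            "A1": "A",
            "A2": "A",
            "B1": "B",
            "B2": "B",
            "D1": "D",
            "D2": "D",
            "F1": "F",
        }
    )


@pytest.fixture
def abd_species_pool() -> dict[str, str]:
    return {"A1": "A", "A2": "A", "B1": "B", "B2": "B", "D1": "D", "D2": "D"}


SPECIES_NEWICK_SMALL = (
    "((((A1:1,A2:1)LCA_A:1,(B1:1,B2:1)LCA_B:1)LCA_AB:1,(D1:2,D2:2)LCA_D:1)"
    "LCA_ABD:1,F1:4)LCA_Brassicaceae;"
)


@pytest.fixture
def small_species_tree():
    from linfam.trees import read_species_tree

    return read_species_tree(SPECIES_NEWICK_SMALL)
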