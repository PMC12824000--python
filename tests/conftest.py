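"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pegl import DnaAlignment, PhyloTree, jc69, simulate_alignment
from pegl.tree import Node, random_tree


@pytest.fixture(scope="session")
def jc():
    return jc69()


@pytest.fixture
def quartet_tree():
    from pegl import parse_newick

    return parse_newick("((a:0.1,b:0.2):0.05,c:0.3,d:0.4);")


@pytest.fixture
def small_alignment():
    return DnaAlignment.from_sequences(
        [("a", "ACGTAC"), ("b", "ACGTAT"), ("c", "ACGAAC"), ("d", "ATGTAC")]
    )


def enumerate_topologies(taxa, bl: float = 0.15) -> list[PhyloTree]:
    """Exhaustive unrooted topologies by sequential edge insertion.

    Independent of the package's random generator: yields all (2m-5)!!
    labelled topologies (3 for m=4, 15 for m=5).
    """
    taxa = list(taxa)
    root = Node()
    for name in taxa[:3]:
        root.add(Node(name=name, length=bl))
    shapes = [root]
    for name in taxa[3:]:
        grown = []
        for shape in shapes:
            n_edges = sum(1 for n in shape.postorder() if n.parent is not None)
            for index in range(n_edges):
                dup = shape.copy()
                edges = [n for n in dup.postorder() if n.parent is not None]
                target = edges[index]
                parent = target.parent
                mid = Node(length=bl)
                parent.children[parent.children.index(target)] = mid
                mid.parent = parent
                mid.add(target)
                mid.add(Node(name=name, length=bl))
                grown.append(dup)
        shapes = grown
    return [PhyloTree(shape) for shape in shapes]


def brute_force_site_lnl(tree, alignment, model) -> np.ndarray:
    """Exhaustive sum over internal-node state assignments.

    The likelihood oracle: enumerates every joint internal state (4^k
    for k internal nodes), multiplying stationary, transition and tip
    probabilities explicitly, averaged over rate categories.  Only
    feasible for tiny trees.
    """
    tip = alignment.partials()
    internals = [n for n in tree.postorder() if not n.is_leaf]
    weights = [((1 - model.p_inv) / len(model.category_rates), r)
               for r in model.category_rates]
    if model.p_inv > 0:
        weights.append((model.p_inv, 0.0))
    out = np.zeros(alignment.n_sites)
    for site in range(alignment.n_sites):
        total = 0.0
        for assignment in itertools.product(range(4), repeat=len(internals)):
            states = {id(node): s for node, s in zip(internals, assignment)}
            for weight, rate in weights:
                prob = model.pi[states[id(tree.root)]]
                for node in tree.postorder():
                    if node.parent is None:
                        continue
                    p_mat = model.transition_matrix(node.length * rate)
                    parent_state = states[id(node.parent)]
                    if node.is_leaf:
                        prob *= p_mat[parent_state] @ tip[node.name][site]
                    else:
                        prob *= p_mat[parent_state, states[id(node)]]
                total += weight * prob
        out[site] = np.log(total)
    return out


def simulated_quartet(seed: int = 5, n: int = 10):
    """A small random quartet tree plus an alignment simulated on it."""
    tree = random_tree(list("abcd"), seed=seed, bl_mean=0.2)
    alignment, _ = simulate_alignment(tree, jc69(), n=n, seed=seed + 1)
    return tree, alignment
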