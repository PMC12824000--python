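"""Unrooted phylogenetic trees, Newick I/O and random-tree ensembles.

Trees are stored with a virtual trifurcating root, the standard
representation of an unrooted binary tree; likelihoods computed from any
virtual rooting agree (pulley principle).  An unrooted binary tree over m
leaves has m - 3 internal branches, which is where branch supports live.

The random-tree generator follows Yule–Harding growth: taxa are shuffled,
a 3-leaf star is formed, and each remaining taxon is attached to a
uniformly chosen pendant edge.  Branch lengths are i.i.d. Exponential.
These ensembles supply the observations of the informativeness
regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

try:  # dendropy >= 5
    from dendropy.dataio.newickreader import NewickReaderError as _NewickError
except Exception:  # pragma: no cover - version fallback
    _NewickError = Exception

import dendropy


class TreeError(ValueError):
    """Raised for malformed trees or Newick strings."""


class Node:
    """Tree node; ``length`` is the branch to the parent (root: ignored)."""

    __slots__ = ("children", "parent", "length", "name", "support")

    def __init__(
        self,
        name: str | None = None,
        length: float = 0.0,
        support: float | None = None,
    ) -> None:
        self.children: list["Node"] = []
        self.parent: "Node" | None = None
        self.length = float(length)
        self.name = name
        self.support = support

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def copy(self) -> "Node":
        dup = Node(self.name, self.length, self.support)
        for child in self.children:
            dup.add(child.copy())
        return dup


class PhyloTree:
    """Unrooted binary tree with taxon-labelled leaves.

    The root is an internal node of degree 3 (degree 2 only in the
    degenerate two-taxon case used for pairwise distance work); every
    other internal node has exactly two children.  Branch lengths are in
    expected substitutions per site and must be finite and non-negative.
    """

    def __init__(self, root: Node) -> None:
        self.root = root
        self._validate()

    def _validate(self) -> None:
        leaves = self.leaves()
        m = len(leaves)
        if m < 2:
            raise TreeError("tree needs at least 2 leaves")
        names = [leaf.name for leaf in leaves]
        if any(not n for n in names):
            raise TreeError("unlabelled leaf")
        if len(set(names)) != m:
            raise TreeError("duplicate leaf labels")
        expected_root_degree = 2 if m == 2 else 3
        if m >= 3 and len(self.root.children) != 3:
            raise TreeError(
                f"root must have degree {expected_root_degree}, "
                f"got {len(self.root.children)}"
            )
        for node in self.root.postorder():
            if node is not self.root:
                if not node.is_leaf and len(node.children) != 2:
                    raise TreeError("internal node is not binary")
                if not np.isfinite(node.length) or node.length < 0:
                    raise TreeError(f"invalid branch length {node.length}")

    # -- structure accessors -------------------------------------------------

    def leaves(self) -> list[Node]:
        return [n for n in self.root.postorder() if n.is_leaf]

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(leaf.name for leaf in self.leaves())

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def edges(self) -> list[Node]:
        """Child endpoints of every branch, in deterministic postorder."""
        return [n for n in self.root.postorder() if n.parent is not None]

    def internal_edges(self) -> list[Node]:
        """Child endpoints of internal branches (m - 3 for m >= 4)."""
        return [n for n in self.edges() if not n.is_leaf]

    def total_length(self) -> float:
        return float(sum(n.length for n in self.edges()))

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    def splits(self) -> frozenset[frozenset[frozenset[str]]]:
        """Normalized non-trivial bipartitions (the unrooted topology)."""
        all_taxa = self.taxa
        out = set()
        for node in self.internal_edges():
            side = frozenset(leaf.name for leaf in node.postorder() if leaf.is_leaf)
            out.add(frozenset((side, all_taxa - side)))
        return frozenset(out)

    # -- Newick --------------------------------------------------------------

    def newick(self, include_support: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length!r}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = repr(node.support)
            return f"({inner}){label}:{node.length!r}"

        inner = ",".join(fmt(c) for c in self.root.children)
        label = ""
        if include_support and self.root.support is not None:
            label = repr(self.root.support)
        return f"({inner}){label};"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.n_leaves} leaves)"


def _from_dendropy(dnode, clamp_negative: bool) -> Node:
    if dnode.is_leaf():
        if dnode.taxon is None or not dnode.taxon.label:
            raise TreeError("unlabelled leaf in Newick")
        node = Node(name=dnode.taxon.label)
    else:
        support = None
        if dnode.label is not None:
            try:
                support = float(dnode.label)
            except ValueError:
                support = None
        node = Node(support=support)
    length = dnode.edge.length
    if length is None:
        length = 0.0
    if length < 0:
        if clamp_negative:
            length = 0.0
        else:
            raise TreeError(f"negative branch length {length}")
    node.length = float(length)
    for child in dnode.child_nodes():
        node.add(_from_dendropy(child, clamp_negative))
    return node


def parse_newick(text: str, clamp_negative: bool = False) -> PhyloTree:
    """Parse a Newick string into an unrooted :class:`PhyloTree`.

    A bifurcating (rooted-style) basal node is suppressed by merging the
    two root edges, so the returned tree always uses the trifurcating
    unrooted representation (except for two-taxon inputs).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except (_NewickError, Exception) as exc:
        if isinstance(exc, TreeError):
            raise
        raise TreeError(f"malformed Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node, clamp_negative)
    n_leaves = sum(1 for n in root.postorder() if n.is_leaf)
    if len(root.children) == 2 and n_leaves >= 3:
        a, b = root.children
        inner = a if not a.is_leaf else b
        outer = b if inner is a else a
        # merge the two basal edges across the suppressed root
        new_root = inner
        new_root.parent = None
        outer.parent = None
        outer.length = a.length + b.length
        new_root.add(outer)
        new_root.length = 0.0
        root = new_root
    return PhyloTree(root)


def write_newick(tree: PhyloTree, include_support: bool = True) -> str:
    """Serialize with full float precision; round-trips losslessly."""
    return tree.newick(include_support=include_support)


# -- random trees ------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_tree(
    taxa: Sequence[str],
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
    bl_mean: float = 0.1,
) -> PhyloTree:
    """Random unrooted binary tree: Yule–Harding topology, Exp lengths.

    Taxa are shuffled, a 3-leaf star is built, and each remaining taxon
    is attached to a uniformly chosen pendant edge.  Every branch length
    is then drawn i.i.d. Exponential(mean=``bl_mean``).  Deterministic
    given the seed.
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise TreeError("random_tree needs at least 3 taxa")
    if bl_mean <= 0:
        raise TreeError("bl_mean must be positive")
    rng = _as_rng(seed)
    order = [taxa[i] for i in rng.permutation(len(taxa))]
    root = Node()
    leaves = [root.add(Node(name=t)) for t in order[:3]]
    for name in order[3:]:
        target = leaves[int(rng.integers(len(leaves)))]
        parent = target.parent
        mid = Node()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        leaves.append(mid.add(Node(name=name)))
    tree = PhyloTree(root)
    for node in tree.edges():
        node.length = float(rng.exponential(bl_mean))
    return tree


@dataclass(frozen=True)
class TreeEnsemble:
    """Ordered collection of random trees over one taxon set.

    This is the "observation" set of the informativeness regression: one
    tree per row of the site log-likelihood matrix.
    """

    trees: tuple[PhyloTree, ...]
    seed: int
    bl_mean: float
    taxa: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.trees) < 2:
            raise TreeError("ensemble needs at least 2 trees")
        taxa = self.trees[0].taxa
        for i, t in enumerate(self.trees):
            if t.taxa != taxa:
                raise TreeError(f"tree {i} spans a different taxon set")
        object.__setattr__(self, "taxa", taxa)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.trees)


def build_ensemble(
    taxa: Sequence[str],
    n_trees: int = 10_000,
    seed: int = 0,
    bl_mean: float = 0.1,
) -> TreeEnsemble:
    """Generate ``n_trees`` random trees (default 10,000).

    Child seeds are spawned deterministically from the master seed via
    ``numpy.random.SeedSequence``, so ensembles are reproducible across
    platforms and tree t is independent of the total ensemble size.
    """
    if n_trees < 2:
        raise TreeError("ensemble needs at least 2 trees")
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_trees)
    trees = tuple(
        random_tree(taxa, np.random.default_rng(child), bl_mean)
        for child in children
    )
    return TreeEnsemble(trees=trees, seed=seed, bl_mean=bl_mean)
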