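"""ML tree search and the parametric aLRT branch-support statistic.

Small-scale maximum-likelihood topology estimation: a neighbor-joining
start on pairwise JC69 distances followed by best-improving
nearest-neighbor-interchange (NNI) hill climbing with branch-length
re-optimization.

The approximate likelihood-ratio test compares, for each internal
branch, the tree's log-likelihood ℓ1 with the better of the two NNI
rearrangements around that branch (ℓ2): statistic = max(0, 2(ℓ1 − ℓ2)).
Under the null of an unresolved branch the statistic follows the
½χ²₀ + ½χ²₁ boundary mixture, so the parametric support is
1 − ½·Pr(χ²₁ ≥ statistic) for a positive statistic and 0 at zero.  By
default only the focal branch is re-optimized when scoring the NNI
alternatives (``full=True`` re-optimizes the five local branches).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from io import StringIO

import numpy as np
from scipy.stats import chi2
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .alignment import BASES, DnaAlignment
from .likelihood import (
    BL_MAX,
    BL_MIN,
    _optimize_edge,
    optimize_branch_lengths,
    total_log_likelihood,
)
from .models import SubstModel
from .tree import Node, PhyloTree, TreeError, parse_newick

logger = logging.getLogger(__name__)


def jc_distance(seq_a: np.ndarray, seq_b: np.ndarray, bl_max: float = BL_MAX) -> float:
    """Jukes–Cantor distance d = −(3/4)·ln(1 − 4p/3) between two rows.

    Only positions where both characters are unambiguous bases are
    compared; a saturated pair (p ≥ 3/4) is clamped to ``bl_max``.
    """
    bases = np.array(list(BASES))
    usable = np.isin(seq_a, bases) & np.isin(seq_b, bases)
    if not usable.any():
        warnings.warn("no comparable sites between a sequence pair; distance 0",
                      RuntimeWarning)
        return 0.0
    p = float((seq_a[usable] != seq_b[usable]).mean())
    if p >= 0.75:
        warnings.warn("saturated sequence pair; distance clamped", RuntimeWarning)
        return bl_max
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


def jc_distance_matrix(alignment: DnaAlignment) -> np.ndarray:
    m = alignment.n_taxa
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dist[i, j] = dist[j, i] = jc_distance(
                alignment.matrix[i], alignment.matrix[j]
            )
    return dist


def nj_tree(alignment: DnaAlignment, model: SubstModel | None = None) -> PhyloTree:
    """Neighbor-joining tree on pairwise JC distances.

    Negative NJ branch lengths are clamped to zero.  Three taxa yield
    the unique star resolution with lengths from the three-point
    formulas.  ``model`` is accepted for interface symmetry; distances
    are always the JC closed form.
    """
    del model
    m = alignment.n_taxa
    if m < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dist = jc_distance_matrix(alignment)
    if m == 3:
        d_ab, d_ac, d_bc = dist[0, 1], dist[0, 2], dist[1, 2]
        lengths = (
            max(0.0, (d_ab + d_ac - d_bc) / 2),
            max(0.0, (d_ab + d_bc - d_ac) / 2),
            max(0.0, (d_ac + d_bc - d_ab) / 2),
        )
        root = Node()
        for taxon, length in zip(alignment.taxa, lengths):
            root.add(Node(name=taxon, length=length))
        return PhyloTree(root)
    dm = DistanceMatrix(dist, ids=list(alignment.taxa))
    skb_tree = _skbio_nj(dm)
    buffer = StringIO()
    skb_tree.write(buffer, format="newick")
    return parse_newick(buffer.getvalue(), clamp_negative=True)


def nni_neighbors(tree: PhyloTree, edge_index: int) -> tuple[PhyloTree, PhyloTree]:
    """The two NNI rearrangements around an internal branch.

    ``edge_index`` indexes :meth:`PhyloTree.internal_edges`.  With the
    focal branch separating subtrees {A, B} from {C, D}, the neighbors
    realize {A, C}|{B, D} and {B, C}|{A, D}.  Branch lengths travel with
    their subtrees; the focal length is kept.
    """
    internal = tree.internal_edges()
    if not 0 <= edge_index < len(internal):
        raise TreeError(
            f"edge index {edge_index} outside 0..{len(internal) - 1} "
            "(terminal branches have no NNI)"
        )

    def swapped(swap_first_child: bool) -> PhyloTree:
        dup = tree.copy()
        child = dup.internal_edges()[edge_index]
        parent = child.parent
        sibling = next(c for c in parent.children if c is not child)
        moving = child.children[0 if swap_first_child else 1]
        parent.children[parent.children.index(sibling)] = moving
        moving.parent = parent
        child.children[0 if swap_first_child else 1] = sibling
        sibling.parent = child
        return PhyloTree(dup.root)

    return swapped(False), swapped(True)


def ml_search(
    alignment: DnaAlignment,
    model: SubstModel,
    seed: int = 0,
    nni_tol: float = 1e-4,
    max_iterations: int = 50,
) -> PhyloTree:
    """NJ start + best-improving NNI hill climb with branch re-optimization.

    Accepted moves never decrease the total log-likelihood; the search
    stops when no rearrangement improves it by more than ``nni_tol``.
    The seed is recorded for provenance only — the search is
    deterministic.
    """
    del seed
    if alignment.n_taxa < 4:
        raise ValueError("ML search needs at least 4 taxa")
    tree = optimize_branch_lengths(nj_tree(alignment), alignment, model)
    best_lnl = total_log_likelihood(tree, alignment, model)
    for iteration in range(max_iterations):
        best_move: PhyloTree | None = None
        move_lnl = best_lnl
        for edge_index in range(len(tree.internal_edges())):
            for neighbor in nni_neighbors(tree, edge_index):
                candidate = optimize_branch_lengths(
                    neighbor, alignment, model, max_rounds=3,
                    warn_on_nonconvergence=False,
                )
                lnl = total_log_likelihood(candidate, alignment, model)
                if lnl > move_lnl + nni_tol:
                    best_move, move_lnl = candidate, lnl
        if best_move is None:
            break
        tree = optimize_branch_lengths(best_move, alignment, model)
        best_lnl = total_log_likelihood(tree, alignment, model)
        logger.info("NNI iteration %d: lnL=%.4f", iteration + 1, best_lnl)
    return tree


@dataclass(frozen=True)
class BranchRecord:
    edge_index: int
    statistic: float
    support: float


@dataclass(frozen=True)
class BranchSupportTree:
    """Tree annotated with per-internal-branch aLRT statistics."""

    tree: PhyloTree
    records: tuple[BranchRecord, ...]

    @property
    def average_support(self) -> float:
        if not self.records:
            raise ValueError("tree has no internal branches")
        return float(np.mean([r.support for r in self.records]))


def alrt_support(statistic: float) -> float:
    """Parametric support from the ½χ²₀ + ½χ²₁ mixture.

    p = ½·Pr(χ²₁ ≥ s) for s > 0 and p = 1 at s = 0; support = 1 − p.
    """
    if statistic <= 0:
        return 0.0
    return float(1.0 - 0.5 * chi2.sf(statistic, df=1))


def alrt_annotate(
    tree: PhyloTree,
    alignment: DnaAlignment,
    model: SubstModel,
    full: bool = False,
) -> BranchSupportTree:
    """aLRT statistic and parametric support for every internal branch.

    The input should be the ML (or a user-supplied locally optimal)
    tree; a negative raw statistic — possible on non-optimal input —
    is clamped to zero with a warning.
    """
    if tree.taxa != frozenset(alignment.taxa):
        raise ValueError("tree and alignment taxa must match exactly")
    internal = tree.internal_edges()
    if not internal:
        raise ValueError("tree has no internal branches")
    tip_partials = alignment.partials()

    def local_edges(work_tree: PhyloTree, edge_index: int) -> list[Node]:
        child = work_tree.internal_edges()[edge_index]
        edges = [child]
        if full:
            edges += list(child.children)
            edges += [c for c in child.parent.children if c is not child]
        return edges

    def optimized_lnl(work_tree: PhyloTree, edge_index: int) -> float:
        work_tree = work_tree.copy()
        lnl = -np.inf
        for node in local_edges(work_tree, edge_index):
            lnl = _optimize_edge(work_tree, tip_partials, model, node, BL_MIN, BL_MAX)
        return lnl

    annotated = tree.copy()
    records = []
    for edge_index in range(len(internal)):
        l1 = optimized_lnl(tree, edge_index)
        l2 = max(
            optimized_lnl(neighbor, edge_index)
            for neighbor in nni_neighbors(tree, edge_index)
        )
        statistic = 2.0 * (l1 - l2)
        if 0 <= statistic < 1e-8:
            # below optimizer precision the branch is unresolved; snap to
            # the boundary case rather than the 0.5 side of the mixture
            statistic = 0.0
        if statistic < 0:
            if statistic < -1e-3:  # beyond optimizer tolerance: a real deficit
                warnings.warn(
                    f"negative aLRT statistic ({statistic:.4g}) on branch "
                    f"{edge_index}: input tree is not locally optimal; "
                    "clamped to 0",
                    RuntimeWarning,
                )
            statistic = 0.0
        support = alrt_support(statistic)
        annotated.internal_edges()[edge_index].support = support
        records.append(BranchRecord(edge_index, statistic, support))
    return BranchSupportTree(tree=annotated, records=tuple(records))


def average_alrt(supported: BranchSupportTree) -> float:
    """Arithmetic mean of parametric supports over internal branches."""
    return supported.average_support
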