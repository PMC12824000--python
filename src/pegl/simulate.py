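"""Synthetic alignments and panels with planted ground truth.

The generator emulates the two divergence regimes of small mammalian
marker datasets — shallow within-species samples dominated by
autapomorphies (star-like trees with short internal branches) and
deeper among-species samples of congeners — together with
codon-position rate heterogeneity (fast third positions), optional
indel-rich regions, and multi-gene panels of 700–2,000 bp.  Every
simulated column carries a truth label (invariant → expected
uninformative, otherwise expected informative), the only oracle
available for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignment import BASES, DnaAlignment
from .models import SubstModel, jc69
from .tree import PhyloTree, random_tree, _as_rng


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth attached to a simulated alignment, column-aligned 1:1."""

    tree: PhyloTree
    site_class: np.ndarray  # "invariant" | "slow" | "fast" per column
    rate: np.ndarray  # per-column rate multiplier (0 for invariant)
    frame: int
    expected_informative: np.ndarray  # bool per column
    seed: int | None

    def __post_init__(self) -> None:
        n = self.site_class.shape[0]
        if self.rate.shape != (n,) or self.expected_informative.shape != (n,):
            raise ValueError("truth arrays must align 1:1 with columns")
        invariant = self.site_class == "invariant"
        if not np.all(self.rate[invariant] == 0):
            raise ValueError("invariant sites must have rate 0")
        if not np.all(self.rate[~invariant] > 0):
            raise ValueError("variable sites must have positive rates")
        if np.any(invariant == self.expected_informative):
            raise ValueError("expected-informative must be the non-invariant sites")


def simulate_yule_tree(
    m: int, depth_scale: float = 0.05, seed: int | np.random.Generator = 0
) -> PhyloTree:
    """Among-species-style random tree.

    Yule–Harding topology with Exponential branch lengths rescaled so
    the mean root-to-tip path equals ``depth_scale`` (default 0.05
    substitutions/site, a congeneric divergence depth).
    """
    if m < 4:
        raise ValueError("need at least 4 taxa")
    if depth_scale <= 0:
        raise ValueError("depth_scale must be positive")
    rng = _as_rng(seed)
    taxa = [f"t{i + 1}" for i in range(m)]
    tree = random_tree(taxa, rng, bl_mean=1.0)
    depths = []
    for leaf in tree.leaves():
        depth, node = 0.0, leaf
        while node.parent is not None:
            depth += node.length
            node = node.parent
        depths.append(depth)
    factor = depth_scale / np.mean(depths)
    for node in tree.edges():
        node.length *= factor
    return tree


def simulate_shallow_tree(
    m: int,
    theta: float = 0.005,
    internal_fraction: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> PhyloTree:
    """Within-species-style tree: long terminals, very short internals.

    Terminal branch lengths are Exponential(mean=``theta``), internal
    branches Exponential(mean=``theta * internal_fraction``), producing
    the star-like, autapomorphy-dominated variation typical of
    population samples.
    """
    if m < 4:
        raise ValueError("need at least 4 taxa")
    if theta <= 0 or internal_fraction <= 0:
        raise ValueError("theta and internal_fraction must be positive")
    rng = _as_rng(seed)
    taxa = [f"t{i + 1}" for i in range(m)]
    tree = random_tree(taxa, rng, bl_mean=1.0)
    for node in tree.edges():
        mean = theta if node.is_leaf else theta * internal_fraction
        node.length = float(rng.exponential(mean))
    return tree


def _evolve(
    tree: PhyloTree,
    model: SubstModel,
    rates: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Markov simulation along the tree; returns leaf state codes."""
    n = rates.shape[0]
    states = {id(tree.root): rng.choice(4, size=n, p=model.pi)}
    leaf_states: dict[str, np.ndarray] = {}
    rate_groups = {r: np.flatnonzero(rates == r) for r in np.unique(rates)}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        parent_states = states.pop(id(node))
        if node.is_leaf:
            leaf_states[node.name] = parent_states
        for child in node.children:
            child_states = parent_states.copy()
            for rate, idx in rate_groups.items():
                if rate == 0 or idx.size == 0:
                    continue
                p_mat = model.transition_matrix(child.length * rate)
                cumulative = p_mat.cumsum(axis=1)
                draws = rng.random(idx.size)
                child_states[idx] = (
                    draws[:, None] > cumulative[parent_states[idx]]
                ).sum(axis=1)
            states[id(child)] = child_states
            stack.append(child)
    return leaf_states


def simulate_alignment(
    tree: PhyloTree,
    model: SubstModel | None = None,
    n: int = 1000,
    p_invariant: float = 0.0,
    codon_rates: tuple[float, float, float] | None = None,
    frame: int = 1,
    seed: int = 0,
    ensure_variable: bool = False,
    max_tries: int = 200,
) -> tuple[DnaAlignment, SyntheticTruth]:
    """Simulate an alignment along ``tree`` with planted site classes.

    ``round(p_invariant * n)`` randomly placed columns are invariant
    (rate 0, identical across taxa); the rest evolve with the rate
    multiplier of their codon position (``codon_rates``, default all 1).
    With ``ensure_variable=True`` each variable-class column is
    redrawn (up to ``max_tries``) until it is observed non-constant, so
    planted labels coincide with realized variation — the setting used
    by recovery experiments.
    """
    if n < 3:
        raise ValueError("need at least 3 sites")
    if not 0 <= p_invariant < 1:
        raise ValueError("p_invariant must lie in [0, 1)")
    model = model or jc69()
    if codon_rates is None:
        codon_rates = (1.0, 1.0, 1.0)
    if any(r <= 0 for r in codon_rates):
        raise ValueError("codon rates must be positive")
    rng = np.random.default_rng(seed)
    taxa = sorted(tree.taxa)

    positions = (np.arange(n) + frame - 1) % 3  # codon position 0..2 per column
    rates = np.array([codon_rates[p] for p in positions])
    n_invariant = int(round(p_invariant * n))
    invariant_idx = rng.choice(n, size=n_invariant, replace=False)
    rates[invariant_idx] = 0.0

    leaf_states = _evolve(tree, model, rates, rng)
    matrix = np.vstack([leaf_states[t] for t in taxa])

    variable_idx = np.flatnonzero(rates > 0)
    if ensure_variable and variable_idx.size:
        for _ in range(max_tries):
            constant = np.all(matrix[:, variable_idx] == matrix[0, variable_idx], axis=0)
            redo = variable_idx[constant]
            if redo.size == 0:
                break
            redo_states = _evolve(tree, model, rates[redo], rng)
            for i, t in enumerate(taxa):
                matrix[i, redo] = redo_states[t]

    base_array = np.array(list(BASES))
    alignment = DnaAlignment(
        taxa=tuple(taxa), matrix=base_array[matrix], frame=frame
    )
    site_class = np.where(
        rates == 0, "invariant", np.where(rates > 1, "fast", "slow")
    ).astype(object)
    truth = SyntheticTruth(
        tree=tree,
        site_class=site_class,
        rate=rates,
        frame=frame,
        expected_informative=rates > 0,
        seed=int(seed),
    )
    return alignment, truth


def inject_indels(
    alignment: DnaAlignment,
    region: tuple[int, int],
    taxa: Sequence[str],
) -> DnaAlignment:
    """Gap out a 1-based inclusive column ``region`` for a taxon subset.

    The alignment length never changes; an empty region (start > end)
    returns the input unchanged.  Emulates the indel-rich stretches that
    combined-level alignments introduce.
    """
    start, end = region
    if start > end:
        return alignment
    if not (1 <= start and end <= alignment.n_sites):
        raise ValueError(f"region {region} outside 1..{alignment.n_sites}")
    unknown = [t for t in taxa if t not in alignment.taxa]
    if unknown:
        raise ValueError(f"unknown taxa: {unknown}")
    matrix = alignment.matrix.copy()
    rows = [alignment.taxa.index(t) for t in taxa]
    matrix[np.ix_(rows, range(start - 1, end))] = "-"
    return DnaAlignment(taxa=alignment.taxa, matrix=matrix, frame=alignment.frame)


def simulate_panel(
    gene_length_range: tuple[int, int] = (700, 2000),
    n_genes: int = 8,
    level: str = "among_species",
    seed: int = 0,
    m: int = 6,
    model: SubstModel | None = None,
    p_invariant: float = 0.25,
    codon_rates: tuple[float, float, float] = (1.0, 0.5, 5.0),
    shared_tree: bool = True,
) -> list[tuple[DnaAlignment, SyntheticTruth]]:
    """Simulate a multi-gene panel at one taxonomic level.

    Gene lengths are uniform over ``gene_length_range`` (default the
    700–2,000 bp window of typical protein-coding markers); the default
    codon rates plant fast third positions, and ``p_invariant`` adds a
    constant fraction of invariant columns on top of whatever sites
    happen not to vary.  One tree is shared across genes unless
    ``shared_tree=False``.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    lo, hi = gene_length_range
    if not 3 <= lo <= hi:
        raise ValueError("invalid gene length range")
    if level not in ("within_species", "among_species"):
        raise ValueError("level must be 'within_species' or 'among_species'")
    rng = np.random.default_rng(seed)

    def new_tree() -> PhyloTree:
        if level == "within_species":
            return simulate_shallow_tree(m, seed=rng)
        return simulate_yule_tree(m, seed=rng)

    tree = new_tree()
    panel = []
    for _ in range(n_genes):
        if not shared_tree:
            tree = new_tree()
        length = int(rng.integers(lo, hi + 1))
        gene_seed = int(rng.integers(2**31))
        panel.append(
            simulate_alignment(
                tree, model=model, n=length, p_invariant=p_invariant,
                codon_rates=codon_rates, seed=gene_seed,
            )
        )
    return panel


def write_truth_tsv(truth: SyntheticTruth, path: str | Path) -> Path:
    """Write ``site  class  rate  expected_informative`` for a gene."""
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("site\tclass\trate\texpected_informative\n")
        for i in range(truth.site_class.shape[0]):
            handle.write(
                f"{i + 1}\t{truth.site_class[i]}\t{truth.rate[i]:g}\t"
                f"{int(truth.expected_informative[i])}\n"
            )
    return path
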