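"""Site-wise phylogenetic likelihoods, branch-length fitting, model choice.

The site log-likelihood of an alignment column given a tree and a
substitution model is computed with the pruning (post-order partial
likelihood) algorithm.  Ambiguous characters and gaps contribute partial
likelihood 1 for every compatible state.  Rate heterogeneity is a
discrete-gamma mixture (equal weights) plus an optional invariant-sites
category.  Per-node partial-likelihood scaling with accumulated log
scalers keeps long alignments and small branch lengths away from
underflow.

Because columns are independent, the tree log-likelihood is exactly the
sum of the site log-likelihoods — the structural identity that makes the
per-tree total a valid regression response for the site features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from .alignment import DnaAlignment
from .models import SubstModel, empirical_frequencies
from .tree import PhyloTree, TreeEnsemble

logger = logging.getLogger(__name__)

BL_MIN = 1e-8
BL_MAX = 10.0


def _check_taxa(tree: PhyloTree, alignment: DnaAlignment) -> None:
    if tree.taxa != frozenset(alignment.taxa):
        raise ValueError(
            "tree and alignment taxa must match exactly; "
            f"tree-only={sorted(tree.taxa - set(alignment.taxa))}, "
            f"alignment-only={sorted(set(alignment.taxa) - tree.taxa)}"
        )


def _prune_category(
    tree: PhyloTree, tip_partials: Mapping[str, np.ndarray],
    model: SubstModel, rate: float,
) -> np.ndarray:
    """Per-site log-likelihood for a single rate category."""
    n = next(iter(tip_partials.values())).shape[0]
    store: dict[int, np.ndarray] = {}
    logscale = np.zeros(n)
    for node in tree.postorder():
        if node.is_leaf:
            store[id(node)] = tip_partials[node.name]
            continue
        part = np.ones((n, 4))
        for child in node.children:
            p_mat = model.transition_matrix(child.length * rate)
            part = part * (store.pop(id(child)) @ p_mat.T)
        scale = part.max(axis=1)
        nz = scale > 0
        part = np.where(nz[:, None], part / np.where(nz, scale, 1.0)[:, None], 0.0)
        with np.errstate(divide="ignore"):
            logscale = logscale + np.where(nz, np.log(np.where(nz, scale, 1.0)), -np.inf)
        store[id(node)] = part
    site_l = store[id(tree.root)] @ model.pi
    with np.errstate(divide="ignore"):
        return np.where(site_l > 0, np.log(np.where(site_l > 0, site_l, 1.0)), -np.inf) + logscale


def _site_lnl(
    tree: PhyloTree, tip_partials: Mapping[str, np.ndarray], model: SubstModel
) -> np.ndarray:
    rates = model.category_rates
    weight = (1.0 - model.p_inv) / len(rates)
    components = [np.log(weight) + _prune_category(tree, tip_partials, model, r)
                  for r in rates]
    if model.p_inv > 0:
        n = next(iter(tip_partials.values())).shape[0]
        prod = np.ones((n, 4))
        for name in tip_partials:
            prod = prod * tip_partials[name]
        l_inv = prod @ model.pi
        with np.errstate(divide="ignore"):
            components.append(
                np.log(model.p_inv)
                + np.where(l_inv > 0, np.log(np.where(l_inv > 0, l_inv, 1.0)), -np.inf)
            )
    if len(components) == 1:
        return components[0]
    return logsumexp(np.vstack(components), axis=0)


def site_log_likelihoods(
    tree: PhyloTree, alignment: DnaAlignment, model: SubstModel
) -> np.ndarray:
    """Log-likelihood of every alignment column on ``tree``.

    The tree's taxon set must equal the alignment's exactly.  A fully
    ambiguous (all-gap) column has likelihood 1, hence log-likelihood 0.
    """
    _check_taxa(tree, alignment)
    lnl = _site_lnl(tree, alignment.partials(), model)
    if not np.all(np.isfinite(lnl)):
        bad = int(np.argwhere(~np.isfinite(lnl))[0]) + 1
        raise ValueError(f"non-finite site log-likelihood at column {bad}")
    return lnl


def total_log_likelihood(
    tree: PhyloTree, alignment: DnaAlignment, model: SubstModel
) -> float:
    """Tree log-likelihood: the exact sum of the site log-likelihoods."""
    return float(site_log_likelihoods(tree, alignment, model).sum())


@dataclass(frozen=True)
class SiteLogLikMatrix:
    """T trees × n sites log-likelihoods plus per-tree totals.

    Rows are the regression observations: feature row t is the site
    log-likelihood vector under tree t and the response is its total.
    """

    site_lnl: np.ndarray
    totals: np.ndarray
    atol: float = field(default=1e-8, compare=False)

    def __post_init__(self) -> None:
        site_lnl = np.asarray(self.site_lnl, dtype=float)
        totals = np.asarray(self.totals, dtype=float)
        if site_lnl.ndim != 2 or totals.shape != (site_lnl.shape[0],):
            raise ValueError("site_lnl must be (T, n) with matching totals")
        if not (np.all(np.isfinite(site_lnl)) and np.all(np.isfinite(totals))):
            raise ValueError("non-finite log-likelihood entries")
        gap = np.abs(site_lnl.sum(axis=1) - totals).max()
        if gap > self.atol:
            raise ValueError(
                f"row-sum identity violated: max |total - sum(sites)| = {gap:.3g}"
            )
        object.__setattr__(self, "site_lnl", site_lnl)
        object.__setattr__(self, "totals", totals)

    @property
    def n_trees(self) -> int:
        return int(self.site_lnl.shape[0])

    @property
    def n_sites(self) -> int:
        return int(self.site_lnl.shape[1])


def compute_sitelh_matrix(
    ensemble: TreeEnsemble,
    alignment: DnaAlignment,
    model: SubstModel,
    progress_every: int = 100,
) -> SiteLogLikMatrix:
    """Site log-likelihood matrix of an alignment over a tree ensemble."""
    if ensemble.taxa != frozenset(alignment.taxa):
        raise ValueError("ensemble and alignment taxa must match exactly")
    tip_partials = alignment.partials()
    rows = np.empty((len(ensemble), alignment.n_sites))
    for t, tree in enumerate(ensemble):
        rows[t] = _site_lnl(tree, tip_partials, model)
        if progress_every and (t + 1) % progress_every == 0:
            logger.info("site likelihoods: %d/%d trees", t + 1, len(ensemble))
    if not np.all(np.isfinite(rows)):
        raise ValueError("non-finite site log-likelihood in ensemble")
    return SiteLogLikMatrix(site_lnl=rows, totals=rows.sum(axis=1))


# -- branch-length optimization ----------------------------------------------


def _scale_rows(part: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scale = part.max(axis=1)
    nz = scale > 0
    safe = np.where(nz, scale, 1.0)
    with np.errstate(divide="ignore"):
        return part / safe[:, None], np.where(nz, np.log(safe), -np.inf)


def _edge_profile(tree, tip_partials, model, focal):
    """Inside/outside likelihood vectors around one branch.

    For the focal edge (parent p, child c) and each rate category,
    returns (outside O at p excluding c's subtree, inside partial of
    c's subtree, accumulated log-scalers), so the total log-likelihood
    as a function of the focal length t is recovered from
    sum_xy O_x P_xy(t) inside_y alone — every other edge's contribution
    is frozen.  The invariant-sites component (rate 0) does not depend
    on branch lengths and is returned separately.
    """
    n = next(iter(tip_partials.values())).shape[0]
    per_category = []
    for rate in model.category_rates:
        down: dict[int, np.ndarray] = {}
        dscale: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                down[id(node)] = tip_partials[node.name]
                dscale[id(node)] = np.zeros(n)
                continue
            part = np.ones((n, 4))
            logscale = np.zeros(n)
            for child in node.children:
                p_mat = model.transition_matrix(child.length * rate)
                part = part * (down[id(child)] @ p_mat.T)
                logscale = logscale + dscale[id(child)]
            part, extra = _scale_rows(part)
            down[id(node)] = part
            dscale[id(node)] = logscale + extra

        outside: dict[int, np.ndarray] = {}
        oscale: dict[int, np.ndarray] = {}
        stack = list(tree.root.children)
        while stack:
            node = stack.pop()
            parent = node.parent
            if parent is tree.root:
                part = np.broadcast_to(model.pi, (n, 4)).copy()
                logscale = np.zeros(n)
            else:
                p_mat = model.transition_matrix(parent.length * rate)
                part = outside[id(parent)] @ p_mat
                logscale = oscale[id(parent)].copy()
            for sibling in parent.children:
                if sibling is node:
                    continue
                p_mat = model.transition_matrix(sibling.length * rate)
                part = part * (down[id(sibling)] @ p_mat.T)
                logscale = logscale + dscale[id(sibling)]
            part, extra = _scale_rows(part)
            outside[id(node)] = part
            oscale[id(node)] = logscale + extra
            stack.extend(node.children)
        per_category.append((
            outside[id(focal)], down[id(focal)],
            oscale[id(focal)] + dscale[id(focal)], rate,
        ))

    inv_lnl = None
    if model.p_inv > 0:
        prod = np.ones((n, 4))
        for name in tip_partials:
            prod = prod * tip_partials[name]
        l_inv = prod @ model.pi
        with np.errstate(divide="ignore"):
            inv_lnl = np.where(l_inv > 0, np.log(np.where(l_inv > 0, l_inv, 1.0)),
                               -np.inf)
    return per_category, inv_lnl


def _profile_lnl(model, per_category, inv_lnl, length: float) -> float:
    weight = (1.0 - model.p_inv) / len(per_category)
    components = []
    for out, inside, logscale, rate in per_category:
        p_mat = model.transition_matrix(length * rate)
        site_l = (out * (inside @ p_mat.T)).sum(axis=1)
        with np.errstate(divide="ignore"):
            lnl = np.where(site_l > 0, np.log(np.where(site_l > 0, site_l, 1.0)),
                           -np.inf) + logscale
        components.append(np.log(weight) + lnl)
    if inv_lnl is not None:
        components.append(np.log(model.p_inv) + inv_lnl)
    if len(components) == 1:
        return float(components[0].sum())
    return float(logsumexp(np.vstack(components), axis=0).sum())


def _optimize_edge(tree, tip_partials, model, node,
                   bl_min: float = BL_MIN, bl_max: float = BL_MAX) -> float:
    """Bounded 1-D optimization of one branch in place; returns final lnL."""
    per_category, inv_lnl = _edge_profile(tree, tip_partials, model, node)

    def neg(x: float) -> float:
        return -_profile_lnl(model, per_category, inv_lnl, float(x))

    current = neg(np.clip(node.length, bl_min, bl_max))
    res = minimize_scalar(neg, bounds=(bl_min, bl_max), method="bounded",
                          options={"xatol": 1e-8})
    if res.fun < current:
        node.length = float(res.x)
        return -float(res.fun)
    node.length = float(np.clip(node.length, bl_min, bl_max))
    return -current


def optimize_branch_lengths(
    tree: PhyloTree,
    alignment: DnaAlignment,
    model: SubstModel,
    tol: float = 1e-6,
    max_rounds: int = 20,
    bl_min: float = BL_MIN,
    bl_max: float = BL_MAX,
    warn_on_nonconvergence: bool = True,
) -> PhyloTree:
    """Iterated per-branch ML optimization of branch lengths.

    Sweeps every branch with a bounded (Brent-style) 1-D search, clamped
    to ``[bl_min, bl_max]``, until the total log-likelihood improves by
    less than ``tol`` or ``max_rounds`` is reached.  Only improving
    updates are accepted, so the returned tree's likelihood is never
    below the input's.
    """
    _check_taxa(tree, alignment)
    tree = tree.copy()
    tip_partials = alignment.partials()
    prev = float(_site_lnl(tree, tip_partials, model).sum())
    for round_no in range(max_rounds):
        lnl = prev
        for node in tree.edges():
            lnl = _optimize_edge(tree, tip_partials, model, node, bl_min, bl_max)
        if lnl - prev < tol:
            prev = lnl
            break
        prev = lnl
    else:
        if warn_on_nonconvergence:
            warnings.warn(
                f"branch-length optimization stopped after {max_rounds} rounds "
                "without meeting the tolerance; returning best tree found",
                RuntimeWarning,
            )
    return tree


# -- model selection ---------------------------------------------------------

DEFAULT_CANDIDATES: tuple[tuple[str, bool], ...] = (
    ("JC69", False), ("JC69", True),
    ("HKY85", False), ("HKY85", True),
    ("GTR", False), ("GTR", True),
)


def fit_substitution_model(
    alignment: DnaAlignment,
    tree: PhyloTree,
    family: str,
    gamma: bool = False,
    gamma_categories: int = 4,
    rounds: int = 2,
) -> tuple[SubstModel, PhyloTree, float]:
    """ML fit of one model family on a fixed topology.

    Base frequencies are empirical (ambiguity-weighted counts); kappa and
    the gamma shape use bounded 1-D searches, GTR exchangeabilities a
    Nelder-Mead search in log space, alternated with branch-length
    sweeps.
    """
    pi = None if family == "JC69" else empirical_frequencies(alignment)
    tip_partials = alignment.partials()

    state = {"kappa": 2.0, "rates": np.ones(6), "alpha": 1.0}

    def build() -> SubstModel:
        return SubstModel(
            family,
            pi=pi,
            kappa=state["kappa"],
            exchangeabilities=state["rates"],
            gamma_shape=state["alpha"] if gamma else None,
            gamma_categories=gamma_categories if gamma else 0,
        )

    current = optimize_branch_lengths(tree, alignment, build(), max_rounds=3,
                                      warn_on_nonconvergence=False)

    def lnl_with(**overrides) -> float:
        state_backup = dict(state)
        state.update(overrides)
        value = float(_site_lnl(current, tip_partials, build()).sum())
        state.update(state_backup)
        return value

    for _ in range(rounds):
        if family == "HKY85":
            res = minimize_scalar(
                lambda lk: -lnl_with(kappa=float(np.exp(lk))),
                bounds=(np.log(0.05), np.log(100.0)), method="bounded",
                options={"xatol": 1e-4},
            )
            state["kappa"] = float(np.exp(res.x))
        elif family == "GTR":
            def neg_rates(log_free: np.ndarray) -> float:
                rates = np.append(np.exp(log_free), 1.0)  # GT fixed at 1
                return -lnl_with(rates=rates)

            res = minimize(neg_rates, np.log(state["rates"][:5]),
                           method="Nelder-Mead",
                           options={"maxiter": 120, "fatol": 1e-3, "xatol": 1e-3})
            state["rates"] = np.append(np.exp(res.x), 1.0)
        if gamma:
            res = minimize_scalar(
                lambda la: -lnl_with(alpha=float(np.exp(la))),
                bounds=(np.log(0.05), np.log(100.0)), method="bounded",
                options={"xatol": 1e-4},
            )
            state["alpha"] = float(np.exp(res.x))
        current = optimize_branch_lengths(current, alignment, build(), max_rounds=2,
                                          warn_on_nonconvergence=False)

    model = build()
    lnl = float(_site_lnl(current, tip_partials, model).sum())
    return model, current, lnl


def select_model(
    alignment: DnaAlignment,
    tree: PhyloTree,
    candidates: Sequence[tuple[str, bool]] | None = None,
    gamma_categories: int = 4,
) -> SubstModel:
    """BIC model choice over a small candidate family sweep.

    BIC = -2 lnL + p·ln(n) with p the free model parameters plus branch
    lengths (shared across candidates).  Ties go to the model with fewer
    parameters.
    """
    if candidates is None:
        candidates = DEFAULT_CANDIDATES
    if not candidates:
        raise ValueError("candidate list is empty")
    n_branches = len(tree.edges())
    n = alignment.n_sites
    scored = []
    for order, (family, gamma) in enumerate(candidates):
        model, _, lnl = fit_substitution_model(
            alignment, tree, family, gamma, gamma_categories
        )
        params = model.n_free_parameters() + n_branches
        bic = -2.0 * lnl + params * np.log(n)
        scored.append((round(bic, 6), params, order, model))
        logger.info("model %-8s lnL=%.4f BIC=%.4f", model.describe(), lnl, bic)
    scored.sort(key=lambda item: (item[0], item[1], item[2]))
    return scored[0][3]


# -- TSV interchange ---------------------------------------------------------


def write_sitelh_tsv(matrix: SiteLogLikMatrix, path: str | Path) -> Path:
    """Write the interchange table: ``tree_id  total_lnL  s1 ... sn``."""
    path = Path(path)
    with open(path, "w") as handle:
        header = ["tree_id", "total_lnL"] + [f"s{i}" for i in range(1, matrix.n_sites + 1)]
        handle.write("\t".join(header) + "\n")
        for t in range(matrix.n_trees):
            cells = [str(t + 1), f"{matrix.totals[t]:.10g}"]
            cells += [f"{v:.10g}" for v in matrix.site_lnl[t]]
            handle.write("\t".join(cells) + "\n")
    return path


def read_sitelh_tsv(path: str | Path) -> SiteLogLikMatrix:
    """Read the interchange table back; validates the row-sum identity
    at the file's 10-significant-digit precision."""
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if data.shape[1] < 3:
        raise ValueError("sitelh table needs tree_id, total and >= 1 site")
    totals = data[:, 1]
    sites = data[:, 2:]
    atol = max(1e-8, 1e-9 * (1.0 + np.abs(totals).max()) * sites.shape[1])
    return SiteLogLikMatrix(site_lnl=sites, totals=totals, atol=atol)
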