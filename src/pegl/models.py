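"""Nucleotide substitution models (JC69, HKY85, GTR) with +Γ and +I.

All models are time-reversible with rate matrix Q_ij = s_ij * π_j
(i ≠ j), rows summing to zero, scaled so the expected rate at
stationarity is one substitution per site — branch lengths are then in
expected substitutions/site.  Among-site rate variation uses the
discrete-gamma mixture with k equal-weight categories whose rates are
the means of the k quantile slices (mean-of-quantiles rule), plus an
optional proportion of invariant sites (rate 0).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.stats import gamma as gamma_dist

from .alignment import DnaAlignment

FAMILIES = ("JC69", "HKY85", "GTR")
#: order of the six exchangeabilities: AC, AG, AT, CG, CT, GT
PAIR_ORDER = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def discrete_gamma_rates(shape: float, k: int) -> np.ndarray:
    """Mean-of-quantiles discretization of Gamma(shape, mean=1) into k rates."""
    if k < 1:
        raise ValueError("need at least one category")
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), shape, scale=1.0 / shape)
    # mean of X over each slice via the Gamma(shape+1) cdf identity
    upper = gamma_dist.cdf(edges[1:], shape + 1, scale=1.0 / shape)
    lower = gamma_dist.cdf(edges[:-1], shape + 1, scale=1.0 / shape)
    rates = k * (upper - lower)
    return rates / rates.mean()  # exact mean 1


class SubstModel:
    """A reversible nucleotide substitution model.

    Parameters
    ----------
    family:
        ``"JC69"``, ``"HKY85"`` or ``"GTR"``.
    pi:
        Stationary base frequencies (A, C, G, T); must be positive and
        sum to 1.  JC69 forces the uniform distribution.
    kappa:
        Transition/transversion rate ratio (HKY85 only).
    exchangeabilities:
        Six symmetric rates in :data:`PAIR_ORDER` (GTR only); GT is
        conventionally the reference and may be left at 1.
    gamma_shape, gamma_categories:
        +Γ heterogeneity; ``gamma_categories=0`` disables it.
    p_inv:
        Proportion of invariant sites in [0, 1).
    """

    def __init__(
        self,
        family: str = "JC69",
        pi: Sequence[float] | None = None,
        kappa: float = 2.0,
        exchangeabilities: Sequence[float] | None = None,
        gamma_shape: float | None = None,
        gamma_categories: int = 0,
        p_inv: float = 0.0,
    ) -> None:
        if family not in FAMILIES:
            raise ValueError(f"unknown model family {family!r}")
        self.family = family
        if family == "JC69" or pi is None:
            pi = np.full(4, 0.25)
        pi = np.asarray(pi, dtype=float)
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("pi must be 4 positive frequencies summing to 1")
        self.pi = pi / pi.sum()
        self.kappa = float(kappa)
        if exchangeabilities is None:
            exchangeabilities = np.ones(6)
        self.exchangeabilities = np.asarray(exchangeabilities, dtype=float)
        if self.exchangeabilities.shape != (6,) or np.any(self.exchangeabilities <= 0):
            raise ValueError("need 6 positive exchangeabilities")
        if not 0 <= p_inv < 1:
            raise ValueError("p_inv must lie in [0, 1)")
        self.p_inv = float(p_inv)
        self.gamma_categories = int(gamma_categories)
        self.gamma_shape = None if gamma_shape is None else float(gamma_shape)
        if self.gamma_categories > 0 and (self.gamma_shape is None or self.gamma_shape <= 0):
            raise ValueError("gamma_shape must be > 0 when categories > 0")

        self.Q = self._build_q()
        # reversible Q diagonalized via the symmetrized form
        sqrt_pi = np.sqrt(self.pi)
        sym = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
        eigval, eigvec = eigh((sym + sym.T) / 2)
        self._eigval = eigval
        self._left = eigvec.T * sqrt_pi[None, :]
        self._right = eigvec / sqrt_pi[:, None]
        if self.gamma_categories > 0:
            self.category_rates = discrete_gamma_rates(
                self.gamma_shape, self.gamma_categories
            )
        else:
            self.category_rates = np.ones(1)

    def _build_q(self) -> np.ndarray:
        s = np.zeros((4, 4))
        if self.family == "JC69":
            rates = np.ones(6)
        elif self.family == "HKY85":
            rates = np.ones(6)
            rates[1] = self.kappa  # AG
            rates[4] = self.kappa  # CT
        else:
            rates = self.exchangeabilities
        for rate, (i, j) in zip(rates, PAIR_ORDER):
            s[i, j] = s[j, i] = rate
        q = s * self.pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -(self.pi * np.diag(q)).sum()
        return q / mean_rate

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows are conditional state distributions."""
        if t < 0:
            raise ValueError("negative time")
        p = self._right @ (np.exp(self._eigval * t)[:, None] * self._left)
        return np.clip(p, 0.0, None)

    def describe(self) -> str:
        name = self.family
        if self.gamma_categories:
            name += f"+G{self.gamma_categories}"
        if self.p_inv:
            name += "+I"
        return name

    def n_free_parameters(self) -> int:
        """Free model parameters (for BIC); excludes branch lengths."""
        count = 0
        if self.family != "JC69":
            count += 3  # base frequencies
        if self.family == "HKY85":
            count += 1
        elif self.family == "GTR":
            count += 5
        if self.gamma_categories > 0:
            count += 1
        if self.p_inv > 0:
            count += 1
        return count

    def __repr__(self) -> str:  # pragma: no cover
        return f"SubstModel({self.describe()})"


def jc69(gamma_shape: float | None = None, gamma_categories: int = 0,
         p_inv: float = 0.0) -> SubstModel:
    return SubstModel("JC69", gamma_shape=gamma_shape,
                      gamma_categories=gamma_categories, p_inv=p_inv)


def hky85(pi: Sequence[float], kappa: float = 2.0,
          gamma_shape: float | None = None, gamma_categories: int = 0,
          p_inv: float = 0.0) -> SubstModel:
    return SubstModel("HKY85", pi=pi, kappa=kappa, gamma_shape=gamma_shape,
                      gamma_categories=gamma_categories, p_inv=p_inv)


def gtr(pi: Sequence[float], exchangeabilities: Sequence[float],
        gamma_shape: float | None = None, gamma_categories: int = 0,
        p_inv: float = 0.0) -> SubstModel:
    return SubstModel("GTR", pi=pi, exchangeabilities=exchangeabilities,
                      gamma_shape=gamma_shape,
                      gamma_categories=gamma_categories, p_inv=p_inv)


def empirical_frequencies(alignment: DnaAlignment, floor: float = 1e-3) -> np.ndarray:
    """Ambiguity-weighted base frequencies counted from the alignment.

    Each character contributes its normalized compatibility vector;
    fully ambiguous characters (gaps, N, ?) are uninformative about
    composition and are skipped.  Frequencies are floored away from zero
    so downstream models stay valid.
    """
    totals = np.zeros(4)
    for vec in alignment.partials().values():
        informative = vec.sum(axis=1) < 4
        if informative.any():
            v = vec[informative]
            totals += (v / v.sum(axis=1, keepdims=True)).sum(axis=0)
    if totals.sum() == 0:
        return np.full(4, 0.25)
    freqs = np.maximum(totals / totals.sum(), floor)
    return freqs / freqs.sum()
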