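"""Gene-panel bookkeeping, comparisons and the percentile bootstrap.

Per-gene metrics mirror the three informativeness readouts used to
compare loci: the proportion of informative sites (PEGL/n), the count
itself, and the average parametric aLRT over internal branches.  Panel
utilities split combined alignments while preserving column
coordinates, relate informative-site counts to gapless length, break
counts down by codon position, profile them along the sequence, and
compare groups of genes with a percentile-bootstrap test on the mean
difference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import GAP, AlignmentError, DnaAlignment


@dataclass(frozen=True)
class PanelRecord:
    """Per-gene metrics at one taxonomic level."""

    gene: str
    level: str  # "within_species" | "among_species"
    n_sites: int
    gapless_length: int
    pegl: int
    proportion: float
    average_alrt: float | None = None
    codon_counts: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.proportion <= 1:
            raise ValueError("proportion outside [0, 1]")
        if self.gapless_length > self.n_sites:
            raise ValueError("gapless length exceeds alignment length")
        if self.codon_counts is not None and sum(self.codon_counts) != self.pegl:
            raise ValueError("codon-position counts must sum to PEGL")


@dataclass(frozen=True)
class GroupComparison:
    """Percentile-bootstrap result for a mean difference between groups."""

    labels: tuple[str, str]
    observed_difference: float
    n_replicates: int
    ci_low: float
    ci_high: float
    seed: int
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("CI endpoints crossed")
        object.__setattr__(
            self, "significant", not (self.ci_low <= 0.0 <= self.ci_high)
        )

    def to_dict(self) -> dict:
        return {
            "groups": list(self.labels),
            "observed_difference": self.observed_difference,
            "n_replicates": self.n_replicates,
            "ci_95": [self.ci_low, self.ci_high],
            "significant": self.significant,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class PanelSummary:
    """Alignment counts implied by a panel design (units × genes)."""

    counts: tuple[tuple[str, int], ...]
    total: int


@dataclass(frozen=True)
class SplitGroup:
    """One group's slice of a combined alignment, coordinates preserved."""

    alignment: DnaAlignment
    gap_only_columns: np.ndarray  # bool (n,), all-gap within this group


def split_alignment(
    combined: DnaAlignment, groups: Mapping[str, Sequence[str]]
) -> dict[str, SplitGroup]:
    """Separate a combined alignment into taxon groups.

    Every group keeps ALL columns of the combined alignment (identity
    coordinate map) so site indices remain comparable across groups;
    columns that are gap-only within a group are flagged, not removed.
    """
    known = set(combined.taxa)
    out: dict[str, SplitGroup] = {}
    for name, taxa in groups.items():
        unknown = [t for t in taxa if t not in known]
        if unknown:
            raise AlignmentError(f"group {name!r} names unknown taxa: {unknown}")
        sub = combined.subset(list(taxa))
        gap_only = (sub.matrix == GAP).all(axis=0)
        out[name] = SplitGroup(alignment=sub, gap_only_columns=gap_only)
    return out


def indel_rich_columns(alignment: DnaAlignment, threshold: float = 0.5) -> np.ndarray:
    """Columns whose gap fraction exceeds ``threshold`` (default 50%)."""
    return (alignment.matrix == GAP).mean(axis=0) > threshold


def gapless_length(alignment: DnaAlignment) -> int:
    """Number of columns containing no gap character in any row."""
    return int((~(alignment.matrix == GAP).any(axis=0)).sum())


@dataclass(frozen=True)
class RegressionResult:
    pearson_r: float
    slope: float
    intercept: float
    p_value: float
    r_squared: float


def length_informativeness_regression(
    records: Sequence[PanelRecord] | tuple[Sequence[float], Sequence[float]],
) -> RegressionResult:
    """Pearson correlation and OLS fit of PEGL on gapless length.

    Accepts panel records or an explicit (lengths, counts) pair; needs
    at least 3 points and non-constant lengths.  The p-value is the
    two-sided t-test on the correlation.
    """
    if records and isinstance(records[0], PanelRecord):
        x = np.array([r.gapless_length for r in records], dtype=float)
        y = np.array([r.pegl for r in records], dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in records)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("regression needs >= 3 (length, count) pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in gapless lengths")
    if np.ptp(y) == 0:
        return RegressionResult(pearson_r=0.0, slope=0.0,
                                intercept=float(y[0]), p_value=1.0,
                                r_squared=0.0)
    fit = stats.linregress(x, y)
    return RegressionResult(
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        r_squared=float(fit.rvalue**2),
    )


def bootstrap_mean_difference(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_replicates: int = 10_000,
    seed: int = 0,
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Percentile-bootstrap test of mean(A) − mean(B).

    Each replicate resamples each group with replacement at its own
    size; the 95% CI is the empirical 2.5/97.5 percentile interval and
    the difference is called significant when the CI excludes zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_replicates < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    mean_a = a[rng.integers(0, a.size, size=(n_replicates, a.size))].mean(axis=1)
    mean_b = b[rng.integers(0, b.size, size=(n_replicates, b.size))].mean(axis=1)
    diffs = mean_a - mean_b
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return GroupComparison(
        labels=labels,
        observed_difference=float(a.mean() - b.mean()),
        n_replicates=int(n_replicates),
        ci_low=float(lo),
        ci_high=float(hi),
        seed=int(seed),
    )


def codon_position_counts(
    mask: Sequence[bool] | np.ndarray, frame: int
) -> tuple[int, int, int]:
    """Informative sites tallied by codon position.

    ``frame`` is the codon position (1, 2 or 3) of column 1; column j
    then has position ((j − 1 + frame − 1) mod 3) + 1.  The three counts
    sum to PEGL by construction.
    """
    if frame not in (1, 2, 3):
        raise ValueError("frame must be 1, 2 or 3")
    mask = np.asarray(mask, dtype=bool)
    sites = np.flatnonzero(mask) + 1
    positions = (sites - 1 + frame - 1) % 3 + 1
    return (
        int((positions == 1).sum()),
        int((positions == 2).sum()),
        int((positions == 3).sum()),
    )


def positional_profile(
    mask: Sequence[bool] | np.ndarray, window: int, step: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window counts of informative sites along the sequence.

    Returns (1-based window start positions, counts).  With
    ``step == window`` (the default) windows tile the sequence and the
    counts sum exactly to PEGL.
    """
    mask = np.asarray(mask, dtype=bool)
    if window < 1:
        raise ValueError("window must be >= 1")
    step = window if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    n = mask.size
    starts = np.arange(1, n + 1, step)
    counts = np.array([mask[s - 1 : s - 1 + window].sum() for s in starts])
    return starts, counts


def panel_manifest(design: Sequence[tuple[str, int, int]]) -> PanelSummary:
    """Alignment counts implied by (dataset, units, genes) triples."""
    counts = []
    for dataset, units, genes in design:
        if units < 1 or genes < 1:
            raise ValueError("units and genes must be >= 1")
        counts.append((dataset, units * genes))
    return PanelSummary(counts=tuple(counts), total=sum(c for _, c in counts))


def summarize_panels(records: Sequence[PanelRecord]) -> pd.DataFrame:
    """Descriptive statistics of proportion and average aLRT per level.

    Standard deviations use the n−1 denominator; a single-record level
    reports a missing sd.
    """
    if not records:
        raise ValueError("no records to summarize")
    frame = pd.DataFrame(
        {
            "level": [r.level for r in records],
            "proportion": [r.proportion for r in records],
            "average_alrt": [r.average_alrt for r in records],
        }
    )
    summary = frame.groupby("level").agg(["mean", "std", "min", "max", "count"])
    summary.columns = ["_".join(c) for c in summary.columns]
    return summary


def write_panel_tsv(records: Sequence[PanelRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("gene\tlevel\tn\tgapless_len\tpegl\tproportion\tavg_alrt\tc1\tc2\tc3\n")
        for r in records:
            c1, c2, c3 = r.codon_counts if r.codon_counts else ("NA", "NA", "NA")
            alrt = "NA" if r.average_alrt is None else f"{r.average_alrt:.6g}"
            handle.write(
                f"{r.gene}\t{r.level}\t{r.n_sites}\t{r.gapless_length}\t"
                f"{r.pegl}\t{r.proportion:.6g}\t{alrt}\t{c1}\t{c2}\t{c3}\n"
            )
    return path


def read_panel_tsv(path: str | Path) -> list[PanelRecord]:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    records = []
    for _, row in frame.iterrows():
        codon = None
        if not pd.isna(row["c1"]):
            codon = (int(row["c1"]), int(row["c2"]), int(row["c3"]))
        records.append(
            PanelRecord(
                gene=str(row["gene"]),
                level=str(row["level"]),
                n_sites=int(row["n"]),
                gapless_length=int(row["gapless_len"]),
                pegl=int(row["pegl"]),
                proportion=float(row["proportion"]),
                average_alrt=None if pd.isna(row["avg_alrt"]) else float(row["avg_alrt"]),
                codon_counts=codon,
            )
        )
    return records


def write_comparison_json(comparison: GroupComparison, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(comparison.to_dict(), indent=2) + "\n")
    return path
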