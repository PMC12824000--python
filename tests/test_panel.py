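"""Panel statistics: splits, regression, bootstrap, codon/positional sums."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pegl import (
    DnaAlignment,
    bootstrap_mean_difference,
    codon_position_counts,
    gapless_length,
    length_informativeness_regression,
    panel_manifest,
    positional_profile,
    split_alignment,
    summarize_panels,
)
from pegl.panel import PanelRecord, indel_rich_columns, read_panel_tsv, write_panel_tsv


@pytest.fixture
def combined():
    return DnaAlignment.from_sequences(
        [
            ("w1", "ACGTAC--GT"),
            ("w2", "ACGTAT--GT"),
            ("w3", "ACCTAC--GT"),
            ("s1", "ACGTACTTGT"),
            ("s2", "AGGTACTAGT"),
            ("s3", "ACGAACTTGT"),
        ]
    )


def test_split_preserves_coordinates_and_flags_gap_only(combined):
    groups = split_alignment(
        combined, {"within": ["w1", "w2", "w3"], "among": ["s1", "s2", "s3"]}
    )
    assert groups["within"].alignment.n_sites == 10
    assert groups["among"].alignment.n_sites == 10
    # columns 7-8 are gap-only in the within group, populated in among
    assert list(np.flatnonzero(groups["within"].gap_only_columns) + 1) == [7, 8]
    assert not groups["among"].gap_only_columns.any()


def test_split_with_single_total_group_is_identity(combined):
    groups = split_alignment(combined, {"all": list(combined.taxa)})
    assert groups["all"].alignment == combined


def test_split_rejects_unknown_taxon(combined):
    with pytest.raises(Exception, match="unknown"):
        split_alignment(combined, {"bad": ["w1", "nope"]})


def test_gapless_length_counts_gap_free_columns(combined):
    assert gapless_length(combined) == 8
    no_gaps = DnaAlignment.from_sequences([("a", "ACGT"), ("b", "ACGT")])
    assert gapless_length(no_gaps) == 4
    all_gapped = DnaAlignment.from_sequences([("a", "-C"), ("b", "A-")])
    assert gapless_length(all_gapped) == 0


def test_indel_rich_flagging_threshold(combined):
    flags = indel_rich_columns(combined.subset(["w1", "w2", "w3", "s1"]))
    assert list(np.flatnonzero(flags) + 1) == [7, 8]  # 3/4 gaps > 50%


def test_regression_recovers_constructed_slope():
    lengths = np.arange(700, 2001, 100)
    counts = np.round(0.30 * lengths)
    fit = length_informativeness_regression((lengths, counts))
    assert fit.pearson_r > 0.999
    assert fit.slope == pytest.approx(0.30, abs=0.01)
    assert fit.p_value < 0.01


def test_regression_on_constant_counts_is_flat():
    fit = length_informativeness_regression(([700, 1000, 1500], [50, 50, 50]))
    assert fit.slope == 0.0
    assert fit.pearson_r == 0.0


def test_regression_needs_three_points():
    with pytest.raises(ValueError):
        length_informativeness_regression(([700, 900], [10, 20]))


def test_bootstrap_identical_groups_not_significant():
    values = [0.3, 0.4, 0.35, 0.5, 0.25]
    result = bootstrap_mean_difference(values, values, n_replicates=1000, seed=4)
    assert result.observed_difference == 0.0
    assert result.ci_low <= 0.0 <= result.ci_high
    assert not result.significant


def test_bootstrap_constant_shift_gives_degenerate_ci():
    a = [12.0] * 6
    b = [2.0] * 6
    result = bootstrap_mean_difference(a, b, n_replicates=500, seed=1)
    assert (result.ci_low, result.ci_high) == (10.0, 10.0)
    assert result.significant


def test_bootstrap_is_deterministic_and_validates():
    a, b = [1.0, 2.0, 3.0], [2.0, 2.5]
    one = bootstrap_mean_difference(a, b, n_replicates=500, seed=9)
    two = bootstrap_mean_difference(a, b, n_replicates=500, seed=9)
    assert (one.ci_low, one.ci_high) == (two.ci_low, two.ci_high)
    with pytest.raises(ValueError):
        bootstrap_mean_difference([], b, n_replicates=500, seed=0)
    with pytest.raises(ValueError):
        bootstrap_mean_difference(a, b, n_replicates=50, seed=0)


def test_codon_counts_examples():
    mask = np.zeros(9, dtype=bool)
    mask[[2, 5, 8]] = True  # columns 3, 6, 9
    assert codon_position_counts(mask, frame=1) == (0, 0, 3)
    assert codon_position_counts(np.zeros(9, dtype=bool), frame=1) == (0, 0, 0)
    # frame shifts the phase: with frame=2 column 3 is position 1
    assert codon_position_counts(mask, frame=2) == (3, 0, 0)
    with pytest.raises(ValueError):
        codon_position_counts(mask, frame=4)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    mask=st.lists(st.booleans(), min_size=1, max_size=200),
    frame=st.sampled_from([1, 2, 3]),
    window=st.integers(min_value=1, max_value=50),
)
def test_codon_and_window_sums_conserve_pegl(mask, frame, window):
    """Conservation: both breakdowns must re-total to the mask count."""
    mask = np.asarray(mask, dtype=bool)
    total = int(mask.sum())
    assert sum(codon_position_counts(mask, frame)) == total
    _, counts = positional_profile(mask, window)  # step defaults to window
    assert counts.sum() == total


def test_positional_profile_examples():
    mask = np.array([True] * 5 + [False] * 5)
    starts, counts = positional_profile(mask, window=5)
    assert list(starts) == [1, 6]
    assert list(counts) == [5, 0]
    _, whole = positional_profile(mask, window=10)
    assert list(whole) == [5]


def test_panel_manifest_counts():
    summary = panel_manifest(
        [("mito_within", 122, 8), ("mito_among", 100, 8), ("nuclear", 8, 100)]
    )
    assert dict(summary.counts) == {
        "mito_within": 976,
        "mito_among": 800,
        "nuclear": 800,
    }
    assert summary.total == 2576
    with pytest.raises(ValueError):
        panel_manifest([("bad", 0, 8)])


def _record(gene, level, proportion, alrt=0.7):
    return PanelRecord(
        gene=gene, level=level, n_sites=100, gapless_length=90,
        pegl=int(proportion * 100), proportion=proportion, average_alrt=alrt,
        codon_counts=None,
    )


def test_summaries_report_sd_with_n_minus_one():
    records = [
        _record("g1", "among_species", 0.2),
        _record("g2", "among_species", 0.4),
        _record("g3", "within_species", 0.3),
    ]
    table = summarize_panels(records)
    among = table.loc["among_species"]
    assert among["proportion_mean"] == pytest.approx(0.3)
    assert among["proportion_std"] == pytest.approx(0.1414, abs=1e-3)
    assert np.isnan(table.loc["within_species"]["proportion_std"])


def test_summaries_constant_proportions_have_zero_sd():
    records = [_record(f"g{i}", "among_species", 0.25) for i in range(4)]
    table = summarize_panels(records)
    assert table.loc["among_species"]["proportion_std"] == 0.0


def test_panel_record_validates_codon_conservation():
    with pytest.raises(ValueError):
        PanelRecord(
            gene="g", level="among_species", n_sites=10, gapless_length=9,
            pegl=5, proportion=0.5, codon_counts=(1, 1, 1),
        )


def test_panel_tsv_roundtrip(tmp_path):
    records = [
        PanelRecord(
            gene="g1", level="among_species", n_sites=300, gapless_length=290,
            pegl=90, proportion=0.3, average_alrt=0.8, codon_counts=(20, 10, 60),
        ),
        PanelRecord(
            gene="g2", level="within_species", n_sites=200, gapless_length=200,
            pegl=20, proportion=0.1, average_alrt=None, codon_counts=None,
        ),
    ]
    path = write_panel_tsv(records, tmp_path / "panel.tsv")
    assert read_panel_tsv(path) == records
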