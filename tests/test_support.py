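"""NJ, NNI, ML search and aLRT branch supports."""

import numpy as np
import pytest
from scipy.stats import chi2

from pegl import (
    DnaAlignment,
    alrt_annotate,
    alrt_support,
    average_alrt,
    ml_search,
    nj_tree,
    nni_neighbors,
    optimize_branch_lengths,
    parse_newick,
    simulate_alignment,
    total_log_likelihood,
)
from pegl.support import BranchRecord, BranchSupportTree, jc_distance
from pegl.tree import TreeError
from tests.conftest import enumerate_topologies


def test_nj_recovers_generating_quartet(jc):
    generating = parse_newick("((a:0.11,b:0.07):0.09,c:0.12,d:0.16);")
    aln, _ = simulate_alignment(generating, jc, n=4000, seed=7)
    tree = nj_tree(aln)
    assert tree.splits() == generating.splits()


def test_nj_three_taxa_star():
    aln = DnaAlignment.from_sequences(
        [("a", "AAAAACCCCC"), ("b", "AAAAACCCCC"), ("c", "AAAAAGGGGG")]
    )
    tree = nj_tree(aln)
    assert tree.n_leaves == 3
    assert len(tree.internal_edges()) == 0
    lengths = {n.name: n.length for n in tree.leaves()}
    assert lengths["a"] == pytest.approx(0.0, abs=1e-12)


def test_nj_identical_sequences_have_zero_lengths():
    aln = DnaAlignment.from_sequences([(t, "ACGTACGT") for t in "abcd"])
    tree = nj_tree(aln)
    assert tree.total_length() == pytest.approx(0.0, abs=1e-12)


def test_saturated_distance_is_clamped():
    a = np.array(list("ACGT" * 5))
    b = np.array(list("CATG" * 5))  # every position differs
    with pytest.warns(RuntimeWarning, match="saturated"):
        assert jc_distance(a, b) == 10.0


def test_quartet_nni_produces_the_other_two_topologies():
    tree = parse_newick("((a:0.1,b:0.1):0.1,c:0.1,d:0.1);")
    one, two = nni_neighbors(tree, 0)
    produced = {one.splits(), two.splits()}
    universe = {t.splits() for t in enumerate_topologies(list("abcd"))}
    assert produced == universe - {tree.splits()}


def test_nni_changes_exactly_one_split():
    tree = parse_newick(
        "(((a:0.1,b:0.1):0.1,c:0.1):0.1,d:0.1,(e:0.1,f:0.1):0.1);"
    )
    for index in range(len(tree.internal_edges())):
        for neighbor in nni_neighbors(tree, index):
            assert len(tree.splits() - neighbor.splits()) == 1
            assert len(neighbor.splits() - tree.splits()) == 1


def test_double_nni_returns_into_neighbor_set():
    tree = parse_newick("((a:0.1,b:0.1):0.1,c:0.1,(d:0.1,e:0.1):0.2);")
    one, _ = nni_neighbors(tree, 0)
    again = {t.splits() for t in nni_neighbors(one, 0)}
    assert tree.splits() in again | {one.splits()}


def test_nni_rejects_out_of_range_edge():
    tree = parse_newick("((a:0.1,b:0.1):0.1,c:0.1,d:0.1);")
    with pytest.raises(TreeError):
        nni_neighbors(tree, 1)


def test_quartet_ml_search_equals_exhaustive_optimum(jc):
    generating = parse_newick("((a:0.05,b:0.05):0.2,c:0.05,d:0.05);")
    aln, _ = simulate_alignment(generating, jc, n=800, seed=3)
    found = ml_search(aln, jc)
    found_lnl = total_log_likelihood(found, aln, jc)
    best_lnl, best_splits = -np.inf, None
    for topo in enumerate_topologies(list("abcd")):
        fitted = optimize_branch_lengths(topo, aln, jc)
        lnl = total_log_likelihood(fitted, aln, jc)
        if lnl > best_lnl:
            best_lnl, best_splits = lnl, fitted.splits()
    assert found.splits() == best_splits
    assert found_lnl == pytest.approx(best_lnl, abs=1e-3)


def test_ml_search_recovers_long_internal_branch_topology(jc):
    generating = parse_newick(
        "((a:0.05,b:0.05):0.2,c:0.05,(d:0.05,e:0.05):0.2);"
    )
    hits = 0
    for rep in range(8):
        aln, _ = simulate_alignment(generating, jc, n=600, seed=400 + rep)
        hits += ml_search(aln, jc).splits() == generating.splits()
    assert hits >= 7


def test_ml_search_improves_on_nj_start(jc):
    generating = parse_newick("((a:0.08,b:0.04):0.1,c:0.09,(d:0.03,e:0.1):0.07);")
    aln, _ = simulate_alignment(generating, jc, n=400, seed=11)
    nj_lnl = total_log_likelihood(
        optimize_branch_lengths(nj_tree(aln), aln, jc), aln, jc
    )
    ml_lnl = total_log_likelihood(ml_search(aln, jc), aln, jc)
    assert ml_lnl >= nj_lnl - 1e-9


def test_alrt_support_closed_forms():
    assert alrt_support(0.0) == 0.0
    # chi-square oracle: Pr(chi2_1 >= 2.706) = 0.10, halved by the mixture
    oracle = 1 - 0.5 * chi2.sf(2.706, df=1)
    assert alrt_support(2.706) == pytest.approx(oracle)
    assert alrt_support(2.706) == pytest.approx(0.95, abs=5e-4)


def test_alrt_support_is_monotone():
    stats = [0.0, 0.5, 1.0, 2.706, 10.0, 100.0]
    supports = [alrt_support(s) for s in stats]
    assert supports == sorted(supports)
    assert 0.0 <= min(supports) and max(supports) <= 1.0


def test_strong_signal_branch_has_high_support(jc):
    generating = parse_newick("((a:0.05,b:0.05):0.25,c:0.05,d:0.05);")
    aln, _ = simulate_alignment(generating, jc, n=2000, seed=21)
    tree = ml_search(aln, jc)
    supported = alrt_annotate(tree, aln, jc)
    assert supported.records[0].support > 0.99
    assert supported.records[0].statistic >= 0.0
    # annotated Newick round-trips with the support label in place
    back = parse_newick(supported.tree.newick())
    assert back.internal_edges()[0].support == pytest.approx(
        supported.records[0].support
    )


def test_star_like_data_has_low_support(jc):
    aln = DnaAlignment.from_sequences(
        [("a", "ACGTACGTAC"), ("b", "ACGTACGTAC"), ("c", "ACGTACGTAC"),
         ("d", "ACGTACGTAT")]
    )
    tree = ml_search(aln, jc)
    supported = alrt_annotate(tree, aln, jc)
    assert supported.records[0].support < 0.5


def _toy_supported(supports):
    tree = parse_newick("((a:0.1,b:0.1):0.1,c:0.1,d:0.1);")
    records = tuple(
        BranchRecord(i, 1.0 if s else 0.0, s) for i, s in enumerate(supports)
    )
    return BranchSupportTree(tree=tree, records=records)


@pytest.mark.parametrize(
    "supports, expected", [([0.8], 0.8), ([1.0, 0.0], 0.5), ([0.0, 0.0], 0.0)]
)
def test_average_alrt(supports, expected):
    assert average_alrt(_toy_supported(supports)) == pytest.approx(expected)
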