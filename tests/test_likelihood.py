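"""Likelihood engine: closed forms, oracle agreement, optimization, BIC."""

import numpy as np
import pytest

from pegl import (
    DnaAlignment,
    build_ensemble,
    compute_sitelh_matrix,
    hky85,
    jc69,
    optimize_branch_lengths,
    parse_newick,
    select_model,
    simulate_alignment,
    site_log_likelihoods,
    total_log_likelihood,
)
from pegl.likelihood import (
    SiteLogLikMatrix,
    fit_substitution_model,
    read_sitelh_tsv,
    write_sitelh_tsv,
)
from pegl.tree import random_tree
from tests.conftest import brute_force_site_lnl, simulated_quartet


def test_identical_pair_at_zero_length_gives_stationary_frequency(jc):
    tree = parse_newick("(a:0.0,b:0.0);")
    aln = DnaAlignment.from_sequences([("a", "A"), ("b", "A")])
    assert site_log_likelihoods(tree, aln, jc)[0] == pytest.approx(np.log(0.25))


def test_all_gap_column_has_zero_log_likelihood(jc):
    tree = parse_newick("(a:0.3,b:0.1);")
    aln = DnaAlignment.from_sequences([("a", "-"), ("b", "-")])
    assert site_log_likelihoods(tree, aln, jc)[0] == pytest.approx(0.0, abs=1e-12)


def test_saturated_pair_approaches_independence(jc):
    tree = parse_newick("(a:10.0,b:10.0);")
    aln = DnaAlignment.from_sequences([("a", "A"), ("b", "C")])
    assert site_log_likelihoods(tree, aln, jc)[0] == pytest.approx(
        np.log(1 / 16), abs=1e-4
    )


@pytest.mark.parametrize(
    "model",
    [
        jc69(),
        hky85(pi=[0.3, 0.2, 0.3, 0.2], kappa=3.0),
        jc69(gamma_shape=0.5, gamma_categories=4),
        jc69(gamma_shape=1.0, gamma_categories=4, p_inv=0.2),
    ],
    ids=["JC", "HKY", "JC+G4", "JC+G4+I"],
)
def test_pruning_matches_exhaustive_enumeration(model):
    tree, aln = simulated_quartet(seed=5, n=10)
    got = site_log_likelihoods(tree, aln, model)
    expected = brute_force_site_lnl(tree, aln, model)
    assert np.abs(got - expected).max() < 1e-10


def test_total_is_exact_sum_and_doubles_with_duplication(jc):
    tree, aln = simulated_quartet(seed=9, n=40)
    site = site_log_likelihoods(tree, aln, jc)
    total = total_log_likelihood(tree, aln, jc)
    assert total == pytest.approx(site.sum(), abs=1e-8)
    doubled = DnaAlignment.from_sequences(
        [(t, aln.sequence(t) * 2) for t in aln.taxa]
    )
    assert total_log_likelihood(tree, doubled, jc) == pytest.approx(
        2 * total, abs=1e-8
    )
    single = DnaAlignment.from_sequences([(t, aln.sequence(t)[0]) for t in aln.taxa])
    assert total_log_likelihood(tree, single, jc) == pytest.approx(
        site_log_likelihoods(tree, single, jc)[0]
    )


def test_likelihood_invariant_to_virtual_rooting(jc):
    """Pulley principle: the same unrooted tree scored from two rootings."""
    one = parse_newick("((a:0.1,b:0.2):0.05,c:0.3,d:0.4);")
    two = parse_newick("((c:0.3,d:0.4):0.05,a:0.1,b:0.2);")
    _, aln = simulated_quartet(seed=13, n=60)
    delta = site_log_likelihoods(one, aln, jc) - site_log_likelihoods(two, aln, jc)
    assert np.abs(delta).max() < 1e-10


def test_gamma_converges_to_homogeneous_at_large_shape(jc):
    tree, aln = simulated_quartet(seed=21, n=80)
    near_flat = jc69(gamma_shape=1e5, gamma_categories=4)
    assert total_log_likelihood(tree, aln, near_flat) == pytest.approx(
        total_log_likelihood(tree, aln, jc), abs=1e-4
    )


def test_taxon_set_mismatch_is_an_error(jc):
    tree = parse_newick("((a:0.1,b:0.1):0.1,c:0.1,d:0.1);")
    aln = DnaAlignment.from_sequences([("a", "A"), ("b", "C"), ("c", "G")])
    with pytest.raises(ValueError, match="taxa"):
        site_log_likelihoods(tree, aln, jc)


def test_sitelh_matrix_rows_follow_tree_order(jc):
    tree, aln = simulated_quartet(seed=3, n=12)
    ensemble = build_ensemble(aln.taxa, 4, seed=8)
    matrix = compute_sitelh_matrix(ensemble, aln, jc, progress_every=0)
    assert matrix.site_lnl.shape == (4, 12)
    assert np.all(matrix.site_lnl <= 1e-9)  # no column can beat likelihood 1
    for t, tree_t in enumerate(ensemble):
        row = site_log_likelihoods(tree_t, aln, jc)
        assert np.allclose(matrix.site_lnl[t], row)


def test_branch_optimization_hits_lower_clamp_for_identical_sequences(jc):
    tree = parse_newick("(a:0.2,b:0.3);")
    aln = DnaAlignment.from_sequences([("a", "ACGTACGT"), ("b", "ACGTACGT")])
    optimized = optimize_branch_lengths(tree, aln, jc)
    assert optimized.total_length() <= 2 * 1e-6


def test_branch_optimization_matches_jc_closed_form(jc):
    """MLE distance for 10% observed differences: -(3/4)ln(1 - 4p/3)."""
    seq_a = "A" * 900 + "C" * 100
    seq_b = "A" * 1000
    aln = DnaAlignment.from_sequences([("a", seq_a), ("b", seq_b)])
    tree = parse_newick("(a:0.05,b:0.05);")
    optimized = optimize_branch_lengths(tree, aln, jc)
    expected = -0.75 * np.log(1 - 4 / 3 * 0.1)
    assert optimized.total_length() == pytest.approx(expected, abs=1e-3)


def test_branch_optimization_never_decreases_likelihood(jc):
    tree, aln = simulated_quartet(seed=31, n=200)
    before = total_log_likelihood(tree, aln, jc)
    after = total_log_likelihood(optimize_branch_lengths(tree, aln, jc), aln, jc)
    assert after >= before


def test_nested_models_have_ordered_likelihoods():
    tree = random_tree(list("abcde"), seed=2, bl_mean=0.1)
    aln, _ = simulate_alignment(tree, jc69(), n=300, seed=4)
    start = random_tree(list("abcde"), seed=5, bl_mean=0.1)
    lnls = {}
    for family, gamma in [("JC69", False), ("HKY85", False), ("GTR", True)]:
        _, _, lnls[(family, gamma)] = fit_substitution_model(
            aln, start, family, gamma
        )
    assert lnls[("GTR", True)] >= lnls[("HKY85", False)] - 1e-6
    assert lnls[("HKY85", False)] >= lnls[("JC69", False)] - 1e-6


def test_single_candidate_is_returned():
    tree = random_tree(list("abcd"), seed=2)
    aln, _ = simulate_alignment(tree, jc69(), n=120, seed=6)
    model = select_model(aln, tree, candidates=[("HKY85", False)])
    assert model.family == "HKY85"
    with pytest.raises(ValueError):
        select_model(aln, tree, candidates=[])


def test_bic_recovers_generating_model():
    """Data simulated under JC69 should select JC69 in most replicates."""
    hits = 0
    for rep in range(6):
        tree = random_tree(list("abcde"), seed=100 + rep, bl_mean=0.08)
        aln, _ = simulate_alignment(tree, jc69(), n=800, seed=200 + rep)
        chosen = select_model(aln, tree)
        hits += chosen.family == "JC69" and chosen.gamma_categories == 0
    assert hits >= 5


def test_sitelh_tsv_roundtrip(tmp_path, jc):
    tree, aln = simulated_quartet(seed=17, n=25)
    ensemble = build_ensemble(aln.taxa, 3, seed=1)
    matrix = compute_sitelh_matrix(ensemble, aln, jc, progress_every=0)
    path = write_sitelh_tsv(matrix, tmp_path / "sitelh.tsv")
    back = read_sitelh_tsv(path)
    assert back.n_trees == 3 and back.n_sites == 25
    assert np.allclose(back.site_lnl, matrix.site_lnl, rtol=1e-9)


def test_sitelh_matrix_rejects_broken_rowsum():
    with pytest.raises(ValueError, match="row-sum"):
        SiteLogLikMatrix(site_lnl=np.array([[-1.0, -2.0]]), totals=np.array([-4.0]))
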