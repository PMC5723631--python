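import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

from syndromevo import (MkModel, PagelModel, Phylogeny, RateModel, fit_mk,
                        marginal_ancestral_states, pagel_correlated_evolution,
                        prune_log_likelihood, simulate_discrete,
                        simulate_yule_tree, transition_probabilities)
from syndromevo.markov import DegenerateDataWarning, PagelResults

from conftest import brute_force_log_likelihood


def two_state(q01, q10):
    return RateModel((0, 1), np.array([[0.0, q01], [q10, 0.0]]))


# ----------------------------------------------------------------------
def test_zero_time_kernel_is_identity():
    np.testing.assert_allclose(
        transition_probabilities(two_state(0.7, 0.3), 0.0), np.eye(2))


def test_long_time_symmetric_kernel_reaches_uniform():
    p = transition_probabilities(two_state(1.0, 1.0), 50.0)
    np.testing.assert_allclose(p, np.full((2, 2), 0.5), atol=1e-12)


def test_two_state_closed_form_matches_matrix_exponential():
    m = two_state(2.0, 1.0)
    p = transition_probabilities(m, 0.5)
    np.testing.assert_allclose(p, expm(m.generator * 0.5), atol=1e-12)
    assert p[0, 0] == pytest.approx((1 + 2 * np.exp(-3 * 0.5)) / 3)


def test_kernel_rows_are_stochastic_for_larger_alphabets():
    rng = np.random.default_rng(0)
    rates = rng.uniform(0.1, 2.0, size=(4, 4))
    m = RateModel(tuple(range(4)), rates)
    for t in (0.1, 1.0, 7.0):
        p = transition_probabilities(m, t)
        np.testing.assert_allclose(p.sum(axis=1), np.ones(4), atol=1e-9)
        np.testing.assert_allclose(p, expm(m.generator * t), atol=1e-9)


def test_negative_branch_length_rejected():
    with pytest.raises(ValueError):
        transition_probabilities(two_state(1, 1), -0.1)


# ----------------------------------------------------------------------
def test_two_tip_zero_branches_forced_likelihood():
    tree = Phylogeny.from_newick("(A:0,B:0);")
    ll = prune_log_likelihood(tree, {"A": 0, "B": 0}, two_state(1.0, 1.0))
    assert ll == pytest.approx(np.log(0.5))


def test_pruning_equals_exhaustive_enumeration_on_small_trees():
    rng = np.random.default_rng(21)
    for _ in range(25):
        n = int(rng.integers(3, 7))
        tree = simulate_yule_tree(n, 1.0, seed=int(rng.integers(1 << 30)))
        model = two_state(rng.uniform(0.1, 2), rng.uniform(0.1, 2))
        tips = {l: int(rng.integers(2)) for l in tree.tip_labels}
        ll = prune_log_likelihood(tree, tips, model)
        oracle = brute_force_log_likelihood(tree, tips, model)
        assert ll == pytest.approx(oracle, abs=1e-10)


def test_pruning_invariant_to_tip_input_order():
    tree = simulate_yule_tree(12, 1.0, seed=5)
    model = two_state(0.4, 0.9)
    tips = {l: i % 2 for i, l in enumerate(tree.tip_labels)}
    ll1 = prune_log_likelihood(tree, tips, model)
    ll2 = prune_log_likelihood(tree, dict(reversed(list(tips.items()))), model)
    assert abs(ll1 - ll2) < 1e-12


def test_missing_tip_state_treated_as_ambiguous():
    tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
    model = two_state(0.5, 0.5)
    ll_missing = prune_log_likelihood(tree, {"A": 0, "B": 0, "C": np.nan}, model)
    ll_sum = np.logaddexp(
        prune_log_likelihood(tree, {"A": 0, "B": 0, "C": 0}, model),
        prune_log_likelihood(tree, {"A": 0, "B": 0, "C": 1}, model),
    )
    assert ll_missing == pytest.approx(ll_sum)


def test_unknown_tip_raises_mapping_error():
    tree = Phylogeny.from_newick("(A:1,B:1);")
    with pytest.raises(KeyError):
        prune_log_likelihood(tree, {"A": 0, "Z": 1}, two_state(1, 1))


# ----------------------------------------------------------------------
def test_fit_respects_zero_constraints():
    tree = simulate_yule_tree(60, 0.45, seed=2)
    model = RateModel(("A", "B"), np.array([[0.0, 0.1], [0.0, 0.0]]),
                      np.array([[False, True], [False, False]]))
    tips = simulate_discrete(tree, model, root_state_policy="A", seed=3)
    if tips.nunique() < 2:
        pytest.skip("degenerate simulation draw")
    fit = fit_mk(tree, tips, states=("A", "B"),
                 constraint_mask=np.array([[False, True], [False, False]]),
                 restarts=3)
    assert fit.rates[1, 0] == 0.0
    assert fit.rates[0, 1] > 0


def test_fit_matches_grid_search_oracle_on_small_tree():
    tree = Phylogeny.from_newick(
        "(((A:1,B:1):1,(C:1,D:1):1):1,(E:2,F:2):1);")
    tips = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 0, "F": 1}
    model = MkModel(tree, tips, states=(0, 1))
    fit = model.fit(restarts=5, seed=0)
    grid = np.exp(np.linspace(np.log(1e-3), np.log(5), 60))
    best_ll = -np.inf
    for a in grid:
        for b in grid:
            ll = model.loglike(np.array([[0.0, a], [b, 0.0]]))
            best_ll = max(best_ll, ll)
    assert fit.log_likelihood >= best_ll - 1e-6


def test_all_tips_same_state_warns_and_hits_boundary():
    tree = simulate_yule_tree(10, 1.0, seed=4)
    tips = pd.Series("A", index=tree.tip_labels)
    with pytest.warns(DegenerateDataWarning):
        fit = MkModel(tree, tips, states=("A", "B")).fit()
    assert fit.rates.max() <= 1e-8 + 1e-15


def test_rate_recovery_on_moderate_tree():
    """Simulation -> fit round trip at a size where ML is reliable."""
    tree = simulate_yule_tree(300, 0.45, seed=8)
    truth = two_state(0.09, 0.10)
    # rescale: tree height ~9, rates ~0.1 -> informative regime
    tips = simulate_discrete(tree, truth, root_state_policy=0, seed=9)
    fit = fit_mk(tree, tips, states=(0, 1), restarts=5, seed=1)
    assert 0.09 / 2.5 < fit.rates[0, 1] < 0.09 * 2.5
    assert 0.10 / 2.5 < fit.rates[1, 0] < 0.10 * 2.5


# ----------------------------------------------------------------------
def test_marginals_zero_length_two_tip_tree():
    tree = Phylogeny.from_newick("(A:0,B:0);")
    marg = marginal_ancestral_states(tree, {"A": 0, "B": 0},
                                     two_state(1.0, 1.0))
    root = marg.iloc[-1]
    assert root[0] == pytest.approx(1.0)
    assert root[1] == pytest.approx(0.0)


def test_marginals_mirrored_configuration_is_symmetric():
    tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    model = two_state(0.6, 0.6)
    m1 = marginal_ancestral_states(tree, {"A": 0, "B": 0, "C": 1, "D": 1}, model)
    m2 = marginal_ancestral_states(tree, {"A": 1, "B": 1, "C": 0, "D": 0}, model)
    root1, root2 = m1.iloc[-1], m2.iloc[-1]
    assert root1[0] == pytest.approx(root2[1])
    np.testing.assert_allclose(m1.to_numpy().sum(axis=1), 1.0, atol=1e-12)


def test_marginals_equal_brute_force_posterior():
    from itertools import product

    rng = np.random.default_rng(33)
    tree = simulate_yule_tree(5, 1.0, seed=13)
    model = two_state(0.8, 0.4)
    q = model.generator
    tips = {l: int(rng.integers(2)) for l in tree.tip_labels}
    marg = marginal_ancestral_states(tree, tips, model)

    pmats = [expm(q * t) for t in tree.blen]
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    tip_assign = {tree.tip_index(l): s for l, s in tips.items()}
    post = {i: np.zeros(2) for i in internal}
    for combo in product(range(2), repeat=len(internal)):
        st = dict(zip(internal, combo))
        st.update(tip_assign)
        p = 0.5
        for i in range(tree.n_nodes):
            if i != tree.root:
                p *= pmats[i][st[tree.parent[i]], st[i]]
        for i in internal:
            post[i][st[i]] += p
    for i in internal:
        expected = post[i] / post[i].sum()
        np.testing.assert_allclose(marg.loc[tree.node_name(i)].to_numpy(),
                                   expected, atol=1e-10)


# ----------------------------------------------------------------------
def test_pagel_dependent_likelihood_nests_independent():
    tree = simulate_yule_tree(60, 0.45, seed=14)
    sx = simulate_discrete(tree, two_state(0.08, 0.05), seed=15)
    sy = simulate_discrete(tree, two_state(0.06, 0.04), seed=16)
    if sx.nunique() < 2 or sy.nunique() < 2:
        pytest.skip("degenerate draw")
    res = PagelModel(tree, sx, sy).fit(restarts=2, seed=0)
    assert res.ll_dependent >= res.ll_independent - 1e-6
    assert res.df == 4
    assert 0.0 <= res.p_value <= 1.0


def test_pagel_requires_two_states_per_character():
    tree = simulate_yule_tree(10, 1.0, seed=17)
    const = pd.Series("A", index=tree.tip_labels)
    varying = pd.Series(["A", "B"] * 5, index=tree.tip_labels)
    with pytest.raises(ValueError):
        PagelModel(tree, const, varying)


def test_pagel_lrt_and_pvalue_arithmetic():
    res = PagelResults(-97.318748, -83.446792, 4,
                       np.zeros(4), np.zeros(8), ())
    assert res.lrt_statistic == pytest.approx(27.743912, abs=1e-6)
    assert res.p_value == pytest.approx(chi2.sf(27.743912, 4), rel=1e-12)


def test_pagel_detects_strongly_dependent_evolution():
    from syndromevo.simulate import dependent_pair_model

    tree = simulate_yule_tree(120, 0.45, seed=18)
    pair = simulate_discrete(tree, dependent_pair_model(),
                             root_state_policy=(0, 0), seed=19)
    sx = pair.map(lambda s: s[0])
    sy = pair.map(lambda s: s[1])
    res = pagel_correlated_evolution(tree, sx, sy, restarts=2, seed=0)
    assert res.p_value < 0.05


def test_stationary_root_prior_option():
    tree = simulate_yule_tree(20, 1.0, seed=20)
    m = two_state(0.3, 0.1)
    tips = simulate_discrete(tree, m, seed=21)
    ll_u = prune_log_likelihood(tree, tips, m, root_prior="uniform")
    ll_s = prune_log_likelihood(tree, tips, m, root_prior="stationary")
    assert np.isfinite(ll_u) and np.isfinite(ll_s)
    assert ll_u != ll_s
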