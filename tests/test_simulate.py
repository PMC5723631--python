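import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, kstest

from syndromevo import (RateModel, SimulationConfig, simulate_brownian,
                        simulate_discrete, simulate_trait_matrix,
                        simulate_yule_tree, spearman_pca,
                        transition_probabilities)
from syndromevo.simulate import (STRATEGY_RATES, dependent_pair_model,
                                 strategy_rate_model)


# ----------------------------------------------------------------------
def test_yule_tree_structure():
    tree = simulate_yule_tree(81, 0.45, seed=0)
    assert tree.n_tips == 81
    assert tree.n_nodes - tree.n_tips == 80  # binary rooted: n-1 internals
    assert tree.is_ultrametric(tol=1e-9)


def test_yule_same_seed_reproduces_newick():
    a = simulate_yule_tree(30, 1.0, seed=7).to_newick()
    b = simulate_yule_tree(30, 1.0, seed=7).to_newick()
    assert a == b
    c = simulate_yule_tree(30, 1.0, seed=8).to_newick()
    assert a != c


def test_yule_expected_root_height():
    lam, n, reps = 1.0, 20, 400
    heights = np.array([
        simulate_yule_tree(n, lam, seed=s).depths().max()
        for s in range(reps)
    ])
    expected = sum(1.0 / k for k in range(2, n + 1)) / lam
    # Var(height) = sum 1/(k*lam)^2
    sd = np.sqrt(sum(1.0 / (k * lam) ** 2 for k in range(2, n + 1)))
    assert abs(heights.mean() - expected) < 3 * sd / np.sqrt(reps)


def test_yule_rejects_bad_parameters():
    with pytest.raises(ValueError):
        simulate_yule_tree(1, 1.0)
    with pytest.raises(ValueError):
        simulate_yule_tree(5, 0.0)


# ----------------------------------------------------------------------
def test_discrete_zero_rates_keep_root_state():
    tree = simulate_yule_tree(20, 1.0, seed=1)
    model = RateModel(("A", "B"), np.zeros((2, 2)))
    tips = simulate_discrete(tree, model, root_state_policy="B", seed=2)
    assert (tips == "B").all()


def test_discrete_high_symmetric_rate_reaches_stationarity():
    tree = simulate_yule_tree(400, 1.0, seed=3)
    model = RateModel((0, 1), np.array([[0.0, 5.0], [5.0, 0.0]]))
    tips = simulate_discrete(tree, model, root_state_policy=0, seed=4)
    freq = (tips == 1).mean()
    assert abs(freq - 0.5) < 3 * 0.5 / np.sqrt(400) + 0.05


def test_discrete_transition_counts_match_kernel():
    """Empirical parent->child tip transitions agree with expm(Q t)."""
    model = RateModel((0, 1), np.array([[0.0, 0.8], [0.5, 0.0]]))
    t = 0.7
    # a star of identical branches: each branch is an independent draw
    n = 4000
    newick = "(" + ",".join(f"t{i}:{t}" for i in range(n)) + ");"
    from syndromevo import Phylogeny

    tree = Phylogeny.from_newick(newick)
    tips = simulate_discrete(tree, model, root_state_policy=0, seed=5)
    counts = tips.value_counts().reindex([0, 1], fill_value=0).to_numpy()
    p = transition_probabilities(model, t)[0]
    res = chisquare(counts, f_exp=n * p)
    assert res.pvalue > 0.01


def test_discrete_reproducible():
    tree = simulate_yule_tree(25, 1.0, seed=6)
    m = RateModel((0, 1), np.array([[0.0, 0.5], [0.5, 0.0]]))
    assert simulate_discrete(tree, m, seed=9).equals(
        simulate_discrete(tree, m, seed=9))


# ----------------------------------------------------------------------
def test_brownian_zero_rate_constant():
    tree = simulate_yule_tree(15, 1.0, seed=10)
    tips = simulate_brownian(tree, 0.0, seed=11, root_value=2.5)
    assert (tips == 2.5).all()


def test_brownian_star_tree_iid_normal():
    n = 300
    from syndromevo import Phylogeny

    newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
    tree = Phylogeny.from_newick(newick)
    tips = simulate_brownian(tree, 1.0, seed=12)
    assert kstest(tips, "norm").pvalue > 0.01


def test_brownian_tip_covariance_matches_shared_paths():
    from syndromevo.phylometrics import bm_covariance

    tree = simulate_yule_tree(6, 1.0, seed=13)
    rate = 0.8
    reps = 1500
    draws = np.array([
        simulate_brownian(tree, rate, seed=s).to_numpy()
        for s in range(reps)
    ])
    emp = np.cov(draws, rowvar=False, bias=True)
    expected = rate * bm_covariance(tree, tree.tip_labels)
    # each covariance entry has sampling sd ~ sqrt((c_ii c_jj + c_ij^2)/reps)
    sd = np.sqrt((np.outer(np.diag(expected), np.diag(expected))
                  + expected ** 2) / reps)
    assert np.all(np.abs(emp - expected) < 4 * sd + 1e-9)


# ----------------------------------------------------------------------
def test_trait_matrix_dimensions_and_missingness():
    fracs = []
    for seed in range(5):
        ds = simulate_trait_matrix(SimulationConfig(seed=seed))
        assert ds.matrix.values.shape == (81, 53)
        fracs.append((~ds.matrix.observed_mask).mean())
    assert abs(np.mean(fracs) - 0.20) < 0.02


def test_trait_matrix_noiseless_traits_identify_latent():
    cfg = SimulationConfig(seed=3, trait_noise_sd=0.0, missing_rate=0.0,
                           qualitative_fraction=0.0)
    ds = simulate_trait_matrix(cfg)
    from scipy.stats import spearmanr

    for name, cols in ds.blocks.items():
        res = spearman_pca(ds.matrix.to_frame()[cols])
        rho = spearmanr(res.scores, ds.latent[name]).statistic
        assert abs(rho) > 0.999


def test_trait_matrix_reproducible_and_truth_shapes():
    a = simulate_trait_matrix(SimulationConfig(seed=4))
    b = simulate_trait_matrix(SimulationConfig(seed=4))
    np.testing.assert_array_equal(a.matrix.observed_mask,
                                  b.matrix.observed_mask)
    np.testing.assert_allclose(
        a.matrix.values[a.matrix.observed_mask],
        b.matrix.values[b.matrix.observed_mask])
    assert a.states.shape == (81, 4)
    assert set(a.states.columns) == set(a.blocks)
    assert a.tree.to_newick() == b.tree.to_newick()


def test_trait_matrix_state_balance_floor():
    for seed in range(6):
        ds = simulate_trait_matrix(SimulationConfig(seed=seed))
        frac = (ds.states == "B").mean()
        assert (frac >= 0.15).all() and (frac <= 0.85).all()


def test_qualitative_traits_use_three_codes():
    ds = simulate_trait_matrix(SimulationConfig(seed=5))
    qual = [t.name for t in ds.matrix.traits if t.kind == "qualitative"]
    assert qual  # default fraction makes some qualitative
    table = ds.matrix.to_frame()
    for c in qual:
        vals = set(table[c].dropna().unique())
        assert vals <= {0.0, 0.5, 1.0}


def test_strategy_scenario_profiles_are_consistent():
    ds = simulate_trait_matrix(SimulationConfig(seed=6,
                                                rate_scenario="strategy"))
    from syndromevo.simulate import STRATEGY_PROFILES

    for sp in ds.strategies.index:
        strat = ds.strategies[sp]
        for name in ds.blocks:
            assert ds.states.loc[sp, name] == STRATEGY_PROFILES[strat][name]


def test_strategy_rate_model_masks_reversals():
    m = strategy_rate_model()
    assert m.rates[m.states.index("A"), m.states.index("B1")] == 0.067
    assert m.rates[m.states.index("A"), m.states.index("B2")] == 0.027
    assert m.rates[m.states.index("B2"), m.states.index("B1")] == 0.014
    assert m.rates[m.states.index("B1"), m.states.index("A")] == 0.0
    assert not m.constraint_mask[m.states.index("B1"), m.states.index("A")]


def test_dependent_pair_model_forbids_double_transitions():
    q = dependent_pair_model().generator
    assert q[0, 3] == 0 and q[3, 0] == 0 and q[1, 2] == 0 and q[2, 1] == 0


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(missing_rate=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(rate_scenario="nope")
    with pytest.raises(ValueError):
        SimulationConfig(n_traits=10)  # blocks exceed total


def test_dataset_write_round_trip(tmp_path):
    ds = simulate_trait_matrix(SimulationConfig(seed=7))
    ds.write(tmp_path)
    from syndromevo import Phylogeny, TraitMatrix

    back = TraitMatrix.read_csv(tmp_path / "traits.csv")
    assert back.species == ds.matrix.species
    tree = Phylogeny.read(tmp_path / "tree.nwk")
    assert tree.tip_labels == ds.tree.tip_labels
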