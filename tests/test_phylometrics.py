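import numpy as np
import pandas as pd
import pytest

from syndromevo import (PhyloANOVA, PhyloPCA, Phylogeny, abouheif_cmean_test,
                        abouheif_proximity, mpd, mpd_null_test, phylo_anova,
                        ppca, simulate_brownian, simulate_yule_tree)


# ----------------------------------------------------------------------
def test_proximity_worked_three_tip_tree(worked_tree):
    prox = abouheif_proximity(worked_tree).to_frame()
    assert prox.loc["A", "B"] == pytest.approx(1 / 2)
    assert prox.loc["A", "C"] == pytest.approx(1 / 4)
    assert prox.loc["B", "C"] == pytest.approx(1 / 4)
    assert np.all(np.diag(prox.to_numpy()) == 0)


def test_proximity_balanced_four_tip_tree(balanced4):
    prox = abouheif_proximity(balanced4).to_frame()
    assert prox.loc["A", "B"] == pytest.approx(1 / 2)
    assert prox.loc["C", "D"] == pytest.approx(1 / 2)
    for a in "AB":
        for b in "CD":
            assert prox.loc[a, b] == pytest.approx(1 / 8)


def test_proximity_star_tree_uniform():
    n = 6
    newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
    tree = Phylogeny.from_newick(newick)
    prox = abouheif_proximity(tree).values
    off = prox[~np.eye(n, dtype=bool)]
    np.testing.assert_allclose(off, 1 / n)


def test_proximity_entries_positive_bounded_and_symmetric(yule81):
    prox = abouheif_proximity(yule81).values
    off = prox[~np.eye(81, dtype=bool)]
    assert np.all(off > 0) and np.all(off <= 1)
    np.testing.assert_allclose(prox, prox.T)


# ----------------------------------------------------------------------
def test_cmean_matches_direct_double_sum(worked_tree):
    # 5-tip hand-checkable case: compute the Moran double sum directly
    tree = Phylogeny.from_newick("(((A:1,B:1):1,C:2):1,(D:2,E:2):1);")
    x = pd.Series([1.0, 2.0, 0.5, -1.0, 3.0], index=list("ABCDE"))
    res = abouheif_cmean_test(x, tree, n_perm=9, seed=0)
    w = abouheif_proximity(tree, list("ABCDE")).normalized().values
    z = x.to_numpy() - x.mean()
    direct = float(z @ w @ z / (z @ z))
    assert res.cmean == pytest.approx(direct, abs=1e-12)


def test_cmean_positive_control_on_caterpillar():
    # depth-graded trait on a strongly imbalanced tree has strong signal
    newick = "t0:1"
    for i in range(1, 15):
        newick = f"({newick},t{i}:{i + 1}):1"
    tree = Phylogeny.from_newick(newick + ";")
    vals = pd.Series(np.arange(15, dtype=float),
                     index=[f"t{i}" for i in range(15)])
    res = abouheif_cmean_test(vals, tree, n_perm=999, seed=1)
    assert res.p_value <= 0.01


def test_cmean_constant_values_rejected(yule81):
    with pytest.raises(ValueError):
        abouheif_cmean_test(pd.Series(1.0, index=yule81.tip_labels), yule81)


# ----------------------------------------------------------------------
def test_ppca_star_tree_single_trait_closed_form():
    n = 12
    newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
    tree = Phylogeny.from_newick(newick)
    rng = np.random.default_rng(2)
    df = pd.DataFrame({"x": rng.normal(size=n)},
                      index=[f"t{i}" for i in range(n)])
    # need >=2 columns is not required for PhyloPCA; single variable allowed
    res = ppca(df, tree)
    assert res.eigenvalues[0] == pytest.approx(-1 / (n - 1), abs=1e-10)


def test_ppca_single_column_equals_quadratic_form(yule81):
    rng = np.random.default_rng(3)
    df = pd.DataFrame({"x": rng.normal(size=81)}, index=yule81.tip_labels)
    res = ppca(df, yule81)
    x = df["x"].to_numpy()
    z = (x - x.mean()) / x.std()
    w = abouheif_proximity(yule81).normalized().values
    direct = z @ ((w + w.T) / 2) @ z / len(z)
    assert res.eigenvalues[0] == pytest.approx(direct, abs=1e-10)


def test_ppca_duplicated_column_loads_symmetrically(yule81):
    vals = simulate_brownian(yule81, 0.1, seed=4)
    df = pd.DataFrame({"a": vals, "b": vals,
                       "c": np.random.default_rng(5).normal(size=81)},
                      index=yule81.tip_labels)
    with pytest.warns(UserWarning):  # rank-deficient by construction
        res = ppca(df, yule81)
    lead = res.axis_loadings["pPC1"]
    assert abs(lead["a"]) == pytest.approx(abs(lead["b"]), abs=1e-8)


def test_ppca_eigenvalue_sum_equals_trace(yule81):
    rng = np.random.default_rng(6)
    df = pd.DataFrame(rng.normal(size=(81, 4)), index=yule81.tip_labels,
                      columns=list("abcd"))
    res = ppca(df, yule81)
    X = df.to_numpy()
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    w = abouheif_proximity(yule81).normalized().values
    h = X.T @ ((w + w.T) / 2) @ X / 81
    assert res.eigenvalues.sum() == pytest.approx(np.trace(h), abs=1e-10)


# ----------------------------------------------------------------------
def test_anova_f_statistic_hand_example(balanced4):
    vals = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("ABCD"))
    groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("ABCD"))
    res = PhyloANOVA(vals, groups, balanced4).fit(n_sim=50, seed=0)
    assert res.f_statistic == pytest.approx(8.0)


def test_anova_star_tree_approaches_parametric_p():
    from scipy.stats import f as fdist

    n = 40
    newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
    tree = Phylogeny.from_newick(newick)
    rng = np.random.default_rng(7)
    vals = pd.Series(rng.normal(size=n), index=tree.tip_labels)
    groups = pd.Series(["a"] * 20 + ["b"] * 20, index=tree.tip_labels)
    res = phylo_anova(vals, groups, tree, n_sim=2000, seed=1)
    parametric = float(fdist.sf(res.f_statistic, 1, n - 2))
    assert abs(res.p_simulated - parametric) < 0.02


def test_anova_phylogenetic_null_is_more_conservative_for_clade_groups():
    tree = simulate_yule_tree(50, 0.45, seed=8)
    vals = simulate_brownian(tree, 0.1, seed=9)
    # group by the basal split: maximal phylogenetic confounding
    root_kids = tree.children[tree.root]
    left = set()
    stack = [root_kids[0]]
    while stack:
        i = stack.pop()
        if not tree.children[i]:
            left.add(tree.labels[i])
        stack.extend(tree.children[i])
    groups = pd.Series(["L" if l in left else "R" for l in vals.index],
                       index=vals.index)
    if groups.value_counts().min() < 2:
        pytest.skip("degenerate basal split")
    from scipy.stats import f as fdist

    res = phylo_anova(vals, groups, tree, n_sim=500, seed=10)
    parametric = float(fdist.sf(res.f_statistic, 1, len(vals) - 2))
    assert res.p_simulated > parametric


def test_anova_validates_groups(balanced4):
    vals = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("ABCD"))
    with pytest.raises(ValueError):
        PhyloANOVA(vals, pd.Series(["g", "g", "g", "g"], index=list("ABCD")),
                   balanced4)
    with pytest.raises(ValueError):
        PhyloANOVA(vals, pd.Series(["a", "b", "b", "b"], index=list("ABCD")),
                   balanced4)


# ----------------------------------------------------------------------
def test_mpd_worked_example(worked_tree):
    assert mpd(worked_tree, ["A", "B", "C"]) == pytest.approx(10 / 3)


def test_mpd_two_tips_is_patristic_distance(worked_tree):
    assert mpd(worked_tree, ["A", "C"]) == pytest.approx(4.0)
    assert mpd(worked_tree, ["C", "A"]) == pytest.approx(4.0)


def test_mpd_unknown_species(worked_tree):
    with pytest.raises(KeyError):
        mpd(worked_tree, ["A", "nope"])


def test_mpd_null_boundaries():
    tree = simulate_yule_tree(12, 1.0, seed=11)
    focal = tree.tip_labels[:4]
    res = mpd_null_test(tree, focal, reps=1, seed=0)
    assert res.p_quantile in (0.0, 1.0)
    assert (res.p_quantile == 1.0) == (res.null_distribution[0] < res.observed)


def test_mpd_cherry_subset_is_clustered():
    tree = simulate_yule_tree(60, 0.45, seed=12)
    # find a cherry: internal node whose children are both tips
    cherry = None
    for i in range(tree.n_nodes):
        kids = tree.children[i]
        if len(kids) == 2 and all(not tree.children[c] for c in kids):
            cherry = [tree.labels[c] for c in kids]
            break
    res = mpd_null_test(tree, cherry, reps=500, seed=1)
    assert res.p_quantile <= 0.05


def test_mpd_null_requires_proper_subset(worked_tree):
    with pytest.raises(ValueError):
        mpd_null_test(worked_tree, ["A", "B", "C"])
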