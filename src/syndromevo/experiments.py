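"""Simulation-based validation experiments for the analysis machinery.

Each function runs a self-contained, seeded experiment that checks one
statistical property of the package: likelihood correctness against
exhaustive enumeration, maximum-likelihood rate recovery, type-I-error
calibration of the correlated-evolution test, exactness of the 1-D 2-means
split, the closed-form phylogenetic-PCA eigenvalue on a star tree,
uniformity of the MPD null quantile, and end-to-end recovery of simulated
syndrome structure by the full pipeline.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from .markov import (RateModel, fit_mk, pagel_correlated_evolution,
                     prune_log_likelihood)
from .phylometrics import mpd_null_test, ppca
from .pipeline import PipelineConfig, run_analysis
from .simulate import (SimulationConfig, simulate_discrete,
                       simulate_trait_matrix, simulate_yule_tree)
from .syndromes import split_two_groups
from .tree import Phylogeny

__all__ = [
    "enumeration_log_likelihood",
    "pruning_enumeration_check",
    "rate_recovery_experiment",
    "pagel_type_i_experiment",
    "two_means_exactness_check",
    "ppca_star_tree_check",
    "mpd_quantile_uniformity",
    "syndrome_recovery_experiment",
    "planted_pair_experiment",
]


# ----------------------------------------------------------------------
def enumeration_log_likelihood(tree: Phylogeny, tip_states: dict,
                               model: RateModel,
                               root_prior: np.ndarray | None = None) -> float:
    """Likelihood by brute-force summation over every assignment of states to
    internal nodes (exponential cost; the independent oracle for pruning)."""
    from scipy.linalg import expm

    k = model.k
    q = model.generator
    if root_prior is None:
        root_prior = np.full(k, 1.0 / k)
    pmats = [expm(q * t) for t in tree.blen]
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    tips = {tree.tip_index(l): model.states.index(s)
            for l, s in tip_states.items()}
    total = 0.0
    for combo in product(range(k), repeat=len(internal)):
        st = dict(zip(internal, combo))
        st.update(tips)
        p = root_prior[st[tree.root]]
        for i in range(tree.n_nodes):
            if i != tree.root:
                p *= pmats[i][st[tree.parent[i]], st[i]]
        total += p
    return float(np.log(total))


def pruning_enumeration_check(n_trees: int = 200, seed: int = 0) -> float:
    """Max |pruning - enumeration| log-likelihood over random 3-6 tip trees."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trees):
        n = int(rng.integers(3, 7))
        tree = simulate_yule_tree(n, 1.0, seed=int(rng.integers(1 << 30)))
        model = RateModel((0, 1), np.array(
            [[0.0, rng.uniform(0.05, 2.0)], [rng.uniform(0.05, 2.0), 0.0]]))
        tips = {l: int(rng.integers(2)) for l in tree.tip_labels}
        delta = abs(prune_log_likelihood(tree, tips, model)
                    - enumeration_log_likelihood(tree, tips, model))
        worst = max(worst, delta)
    return worst


# ----------------------------------------------------------------------
def rate_recovery_experiment(n_reps: int = 50, n_tips: int = 500,
                             q01: float = 0.09, q10: float = 0.10,
                             birth_rate: float = 0.3, factor: float = 1.5,
                             restarts: int = 3, seed: int = 0) -> dict:
    """Simulate a 2-state character on Yule trees and refit by ML; report the
    fraction of replicates with both rates within `factor` of truth.

    The default tree scale puts the root-to-tip height at roughly four times
    the chain's mixing time 1/(q01+q10), so both rates are identifiable."""
    rng = np.random.default_rng(seed)
    truth = RateModel((0, 1), np.array([[0.0, q01], [q10, 0.0]]))
    hits = 0
    estimates = []
    for _ in range(n_reps):
        tree = simulate_yule_tree(n_tips, birth_rate,
                                  seed=int(rng.integers(1 << 30)))
        tips = simulate_discrete(tree, truth, root_state_policy=0,
                                 seed=int(rng.integers(1 << 30)))
        if tips.nunique() < 2:
            continue
        fit = fit_mk(tree, tips, states=(0, 1), restarts=restarts,
                     seed=int(rng.integers(1 << 30)))
        a, b = fit.rates[0, 1], fit.rates[1, 0]
        estimates.append((a, b))
        if (q01 / factor <= a <= q01 * factor
                and q10 / factor <= b <= q10 * factor):
            hits += 1
    n_eff = len(estimates)
    return {"fraction_within_factor": hits / n_eff, "n": n_eff,
            "estimates": estimates}


def pagel_type_i_experiment(n_reps: int = 200, n_tips: int = 200,
                            q01: float = 0.09, q10: float = 0.10,
                            birth_rate: float = 0.45, alpha: float = 0.05,
                            restarts: int = 2, seed: int = 0) -> dict:
    """Simulate two independently evolving binary characters and count how
    often the correlated-evolution LRT rejects at `alpha` (type-I error)."""
    rng = np.random.default_rng(seed)
    model = RateModel((0, 1), np.array([[0.0, q01], [q10, 0.0]]))
    rejections = 0
    n_eff = 0
    pvals = []
    while n_eff < n_reps:
        tree = simulate_yule_tree(n_tips, birth_rate,
                                  seed=int(rng.integers(1 << 30)))
        sx = simulate_discrete(tree, model, seed=int(rng.integers(1 << 30)))
        sy = simulate_discrete(tree, model, seed=int(rng.integers(1 << 30)))
        if sx.nunique() < 2 or sy.nunique() < 2:
            continue
        n_eff += 1
        p = pagel_correlated_evolution(tree, sx, sy, restarts=restarts,
                                       seed=int(rng.integers(1 << 30))).p_value
        pvals.append(p)
        rejections += p < alpha
    return {"rejection_rate": rejections / n_eff, "n": n_eff, "pvals": pvals}


# ----------------------------------------------------------------------
def two_means_exactness_check(n_vectors: int = 1000, seed: int = 0) -> int:
    """Count disagreements between the implemented split and an exhaustive
    breakpoint search minimizing within-group variance."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_vectors):
        n = int(rng.integers(2, 40))
        x = rng.normal(scale=rng.uniform(0.5, 3.0), size=n)
        got = split_two_groups(pd.Series(x))
        xs = np.sort(x)
        best, cut = np.inf, None
        for i in range(1, n):
            if xs[i] == xs[i - 1]:
                continue
            lo, hi = xs[:i], xs[i:]
            ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
            if ss < best:
                best, cut = ss, 0.5 * (xs[i - 1] + xs[i])
        expected = np.where(x > cut, "B", "A")
        if list(got) != list(expected):
            mismatches += 1
    return mismatches


def ppca_star_tree_check(n: int = 12, seed: int = 0) -> dict:
    """On a star tree the row-normalized proximity is (J - I)/(n - 1), so a
    single standardized trait has the closed-form eigenvalue -1/(n-1)."""
    newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
    tree = Phylogeny.from_newick(newick)
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"x": rng.normal(size=n)},
                      index=[f"t{i}" for i in range(n)])
    res = ppca(df, tree)
    return {"eigenvalue": float(res.eigenvalues[0]),
            "expected": -1.0 / (n - 1)}


def mpd_quantile_uniformity(n_replicates: int = 500, pool_tips: int = 60,
                            subset_size: int = 15, reps: int = 200,
                            seed: int = 0) -> dict:
    """Random focal subsets should give uniform null quantiles; returns the
    KS p-value against the uniform distribution."""
    from scipy.stats import kstest

    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(pool_tips, 0.45, seed=seed)
    labels = np.array(tree.tip_labels)
    ps = []
    for _ in range(n_replicates):
        focal = rng.choice(labels, size=subset_size, replace=False)
        res = mpd_null_test(tree, list(focal), reps=reps,
                            seed=int(rng.integers(1 << 30)))
        ps.append(res.p_quantile)
    ks = kstest(ps, "uniform")
    return {"ks_pvalue": float(ks.pvalue), "quantiles": ps}


# ----------------------------------------------------------------------
def _pipeline_config(seed: int) -> PipelineConfig:
    return PipelineConfig(tree="", traits="", syndromes="", seed=seed,
                          mk_restarts=3, pagel_restarts=3,
                          kmeans_restarts=20)


def syndrome_recovery_experiment(n_seeds: int = 20, seed: int = 0) -> dict:
    """Run the full trait -> syndrome -> two-group pipeline on the default
    synthetic dataset and score recovered binary states against the
    generator's truth. Returns per-seed and overall mean accuracy."""
    per_seed = []
    for i in range(n_seeds):
        ds = simulate_trait_matrix(SimulationConfig(seed=seed + i))
        report = run_analysis(ds.matrix, ds.tree, ds.definitions,
                              config=_pipeline_config(seed + i))
        accs = []
        for name in ds.blocks:
            rec = pd.Series(report.syndromes[name]["states"])
            truth = ds.states[name].reindex(rec.index)
            accs.append(float((rec == truth).mean()))
        per_seed.append(float(np.mean(accs)))
    return {"mean_accuracy": float(np.mean(per_seed)), "per_seed": per_seed}


def planted_pair_experiment(n_seeds: int = 20, seed: int = 100,
                            alpha: float = 0.05) -> dict:
    """Simulate one syndrome pair under dependent evolution (others
    independent), run the full pipeline, and check that the planted pair is
    detected (p < alpha) while at least 4 of the 5 remaining pairs are not."""
    successes = 0
    detected = 0
    rows = []
    for i in range(n_seeds):
        ds = simulate_trait_matrix(SimulationConfig(
            seed=seed + i, rate_scenario="dependent_pair"))
        report = run_analysis(ds.matrix, ds.tree, ds.definitions,
                              config=_pipeline_config(seed + i))
        planted = frozenset(ds.config.dependent_pair)
        pv = {frozenset(p["pair"]): p["p_value"] for p in report.pagel}
        p_planted = pv[planted]
        others = [v for k, v in pv.items() if k != planted]
        hit = p_planted < alpha
        quiet = sum(v > alpha for v in others) >= 4
        detected += hit
        successes += hit and quiet
        rows.append({"p_planted": p_planted,
                     "others_above_alpha": int(sum(v > alpha for v in others))})
    return {"success_rate": successes / n_seeds,
            "detection_rate": detected / n_seeds,
            "rows": rows}
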