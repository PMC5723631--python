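"""Phylogenetically structured statistics.

* Abouheif proximity matrix and Cmean permutation test of phylogenetic signal.
* Phylogenetic PCA (pPCA): eigenanalysis of the phylogenetically lagged
  covariance of standardized traits; positive eigenvalues flag global
  (clade-level) structure, negative ones local (tip-contrast) structure.
* Phylogenetic ANOVA: a classical one-way F statistic referred to a null
  distribution of F values from Brownian-motion simulations on the tree.
* Mean pairwise patristic distance (MPD) and its random-subset null model for
  phylogenetic representativeness of a species sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import Phylogeny

__all__ = [
    "ProximityMatrix",
    "abouheif_proximity",
    "abouheif_cmean_test",
    "AbouheifResult",
    "PhyloPCA",
    "PPCAResult",
    "ppca",
    "PhyloANOVA",
    "PhyloAnovaResult",
    "phylo_anova",
    "mpd",
    "mpd_null_test",
    "MPDResult",
]


# ----------------------------------------------------------------------
@dataclass
class ProximityMatrix:
    """Species x species Abouheif proximity (zero diagonal), optionally
    row-normalized."""

    values: np.ndarray
    labels: list
    row_normalized: bool = False

    def normalized(self) -> "ProximityMatrix":
        if self.row_normalized:
            return self
        w = self.values / self.values.sum(axis=1, keepdims=True)
        return ProximityMatrix(w, self.labels, True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def abouheif_proximity(tree: Phylogeny, labels=None) -> ProximityMatrix:
    """Abouheif proximity between tips i and j: the reciprocal of the product
    of direct-descendant counts over the interior nodes on the i-j path
    (endpoints excluded, MRCA included). Diagonal is zero."""
    if labels is None:
        labels = tree.tip_labels
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips")
    idx = [tree.tip_index(l) for l in labels]
    ndesc = np.array([max(len(c), 1) for c in tree.children], dtype=float)
    paths = {i: tree.path_to_root(i) for i in idx}
    ranks = {i: {n: r for r, n in enumerate(p)} for i, p in paths.items()}
    n = len(idx)
    out = np.zeros((n, n))
    for a in range(n):
        pa = paths[idx[a]]
        for b in range(a + 1, n):
            rb = ranks[idx[b]]
            m = next(node for node in pa if node in rb)  # MRCA
            interior = pa[1:pa.index(m)] + paths[idx[b]][1:rb[m]] + [m]
            out[a, b] = out[b, a] = 1.0 / np.prod(ndesc[interior])
    return ProximityMatrix(out, list(labels))


@dataclass
class AbouheifResult:
    """Cmean phylogenetic-signal statistic with its permutation p-value."""

    cmean: float
    p_value: float
    n_perm: int
    null_distribution: np.ndarray

    def summary(self) -> str:
        return (f"Abouheif Cmean = {self.cmean:.4f}, "
                f"p = {self.p_value:.4g} ({self.n_perm} permutations)")


def _cmean(w: np.ndarray, x: np.ndarray) -> float:
    z = x - x.mean()
    return float(z @ w @ z / (z @ z))


def abouheif_cmean_test(values, tree: Phylogeny, n_perm: int = 999,
                        seed: int = 0) -> AbouheifResult:
    """Permutation test of phylogenetic autocorrelation: Moran-style Cmean
    with row-normalized Abouheif proximity; p = (1 + #{null >= obs}) /
    (n_perm + 1), one-sided for positive signal."""
    s = pd.Series(values, dtype=float)
    x = s.to_numpy()
    if np.allclose(x, x[0]):
        raise ValueError("values are constant; Cmean undefined")
    w = abouheif_proximity(tree, list(s.index)).normalized().values
    obs = _cmean(w, x)
    rng = np.random.default_rng(seed)
    null = np.array([_cmean(w, rng.permutation(x)) for _ in range(n_perm)])
    p = (1.0 + np.sum(null >= obs)) / (n_perm + 1.0)
    return AbouheifResult(obs, float(p), n_perm, null)


# ----------------------------------------------------------------------
@dataclass
class PPCAResult:
    """Phylogenetic PCA decomposition.

    eigenvalues are signed and sorted descending; a positive value means the
    axis captures variance that is phylogenetically autocorrelated (global
    structure), a negative one variance concentrated in contrasts between
    close relatives (local structure).
    """

    eigenvalues: np.ndarray
    axis_loadings: pd.DataFrame   # variable x axis
    species_scores: pd.DataFrame  # species x axis

    @property
    def global_axes(self) -> list[str]:
        return [c for c, e in zip(self.axis_loadings.columns, self.eigenvalues)
                if e > 0]

    def summary(self) -> str:
        lines = ["Phylogenetic PCA", "=" * 44,
                 "eigenvalues (global > 0 > local):"]
        for c, e in zip(self.axis_loadings.columns, self.eigenvalues):
            lines.append(f"  {c}: {e:+.4f}")
        return "\n".join(lines)


class PhyloPCA:
    """pPCA of a complete species x variable grid against a tree.

    Columns are centered and scaled (population sd); the decomposition is the
    eigenanalysis of H = (1/n) X' ((W + W') / 2) X with W the row-normalized
    Abouheif proximity, so each axis maximizes the product of variance and
    phylogenetic autocorrelation (positive end) or anti-autocorrelation
    (negative end).
    """

    def __init__(self, data: pd.DataFrame, tree: Phylogeny):
        if data.isna().any().any():
            raise ValueError("grid must be fully observed")
        self.data = data
        self.tree = tree

    def fit(self) -> PPCAResult:
        X = self.data.to_numpy(dtype=float)
        n, m = X.shape
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant column in pPCA input")
        X = (X - X.mean(axis=0)) / sd
        w = abouheif_proximity(self.tree, list(self.data.index)).normalized().values
        h = X.T @ ((w + w.T) / 2.0) @ X / n
        evals, evecs = np.linalg.eigh(h)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        rank = np.linalg.matrix_rank(X)
        if rank < m:
            import warnings

            warnings.warn(f"input grid has rank {rank} < {m}; trailing axes "
                          "are numerically degenerate", UserWarning)
        # sign convention: make each axis's largest-|loading| entry negative-
        # free, i.e. orient so the loading sum is net positive
        for j in range(m):
            if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
                evecs[:, j] = -evecs[:, j]
        axes = [f"pPC{i + 1}" for i in range(m)]
        return PPCAResult(
            eigenvalues=evals,
            axis_loadings=pd.DataFrame(evecs, index=self.data.columns,
                                       columns=axes),
            species_scores=pd.DataFrame(X @ evecs, index=self.data.index,
                                        columns=axes),
        )


def ppca(data: pd.DataFrame, tree: Phylogeny) -> PPCAResult:
    """Convenience wrapper: fit a :class:`PhyloPCA`."""
    return PhyloPCA(data, tree).fit()


# ----------------------------------------------------------------------
@dataclass
class PhyloAnovaResult:
    """One-way F statistic with a Brownian-simulation p-value."""

    f_statistic: float
    p_simulated: float
    n_simulations: int
    bm_rate: float
    group_means: pd.Series

    def summary(self) -> str:
        gm = ", ".join(f"{k}={v:.3g}" for k, v in self.group_means.items())
        return (f"Phylogenetic ANOVA: F = {self.f_statistic:.4f}, "
                f"simulated p = {self.p_simulated:.4g} "
                f"({self.n_simulations} BM simulations, rate {self.bm_rate:.4g}); "
                f"group means: {gm}")


def _oneway_f(x: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(x)
    grand = x.mean()
    ssb = 0.0
    ssw = 0.0
    for g in range(n_groups):
        xg = x[codes == g]
        ssb += len(xg) * (xg.mean() - grand) ** 2
        ssw += ((xg - xg.mean()) ** 2).sum()
    df1, df2 = n_groups - 1, n - n_groups
    return (ssb / df1) / (ssw / df2)


def bm_covariance(tree: Phylogeny, labels) -> np.ndarray:
    """Brownian tip covariance structure: shared root-to-MRCA path lengths."""
    idx = [tree.tip_index(l) for l in labels]
    depth = tree.depths()
    n = len(idx)
    c = np.empty((n, n))
    for a in range(n):
        c[a, a] = depth[idx[a]]
        for b in range(a + 1, n):
            c[a, b] = c[b, a] = depth[tree.mrca(idx[a], idx[b])]
    return c


def _bm_mle_rate(c: np.ndarray, x: np.ndarray) -> float:
    """ML Brownian rate: GLS residual quadratic form / n under the shared
    path-length covariance."""
    n = len(x)
    cinv = np.linalg.inv(c)
    one = np.ones(n)
    mu = (one @ cinv @ x) / (one @ cinv @ one)
    r = x - mu
    return float(r @ cinv @ r / n)


class PhyloANOVA:
    """Two-level phylogenetic ANOVA of a continuous trait.

    The F statistic is the textbook one-way value; the null distribution is
    built by simulating the trait under Brownian motion on the tree (rate
    fitted to the observed values by ML) with group labels held fixed, so the
    test accounts for the non-independence of related species.
    """

    def __init__(self, values, groups, tree: Phylogeny):
        self.values = pd.Series(values, dtype=float)
        self.groups = pd.Series(groups).reindex(self.values.index)
        levels = sorted(self.groups.dropna().unique(), key=str)
        if len(levels) != 2:
            raise ValueError(f"expected a two-level factor, got {levels}")
        counts = self.groups.value_counts()
        if counts.min() < 2:
            raise ValueError("each group needs at least 2 members")
        if np.allclose(self.values, self.values.iloc[0]):
            raise ValueError("values are constant")
        self.levels = levels
        self.tree = tree

    def fit(self, n_sim: int = 1000, seed: int = 0) -> PhyloAnovaResult:
        codes = self.groups.map({l: i for i, l in enumerate(self.levels)}).to_numpy()
        x = self.values.to_numpy()
        f_obs = _oneway_f(x, codes, 2)
        c = bm_covariance(self.tree, list(self.values.index))
        rate = _bm_mle_rate(c, x)
        # draw the BM null directly from its tip covariance (rate * C)
        chol = np.linalg.cholesky(rate * c + 1e-12 * np.eye(len(x)))
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_sim):
            xs = chol @ rng.standard_normal(len(x))
            if _oneway_f(xs, codes, 2) >= f_obs:
                exceed += 1
        gm = self.values.groupby(self.groups).mean()
        return PhyloAnovaResult(float(f_obs), exceed / n_sim, n_sim, rate, gm)


def phylo_anova(values, groups, tree: Phylogeny, n_sim: int = 1000,
                seed: int = 0) -> PhyloAnovaResult:
    """Convenience wrapper: fit a :class:`PhyloANOVA`."""
    return PhyloANOVA(values, groups, tree).fit(n_sim=n_sim, seed=seed)


# ----------------------------------------------------------------------
def mpd(tree: Phylogeny, subset) -> float:
    """Mean patristic (branch-length) distance over all unordered pairs of
    the subset's tips."""
    subset = list(subset)
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 species")
    d = tree.patristic_matrix(subset)
    n = len(subset)
    iu = np.triu_indices(n, 1)
    return float(d[iu].mean())


@dataclass
class MPDResult:
    """Observed MPD against a random-subset null.

    p_quantile is the proportion of null MPDs strictly below the observed
    value: small values mean the focal species are phylogenetically clustered,
    values near the middle mean they are a representative random sample.
    """

    observed: float
    null_distribution: np.ndarray
    p_quantile: float

    def summary(self) -> str:
        return (f"MPD = {self.observed:.4f}, quantile within "
                f"{len(self.null_distribution)} random subsets: "
                f"p = {self.p_quantile:.3f}")


def mpd_null_test(tree: Phylogeny, focal_subset, reps: int = 1000,
                  seed: int = 0) -> MPDResult:
    """Compare the focal subset's MPD with `reps` equal-size subsets drawn
    without replacement from the tree's tips; ties count against clustering
    (strict 'lower than')."""
    focal = list(focal_subset)
    pool = tree.tip_labels
    if len(focal) >= len(pool):
        raise ValueError("focal subset must be smaller than the tip pool")
    dist = tree.patristic_matrix()
    pos = {l: i for i, l in enumerate(pool)}
    iu_cache = np.triu_indices(len(focal), 1)

    def subset_mpd(indices):
        sub = dist[np.ix_(indices, indices)]
        return float(sub[iu_cache].mean())

    observed = subset_mpd([pos[l] for l in focal])
    rng = np.random.default_rng(seed)
    null = np.array([
        subset_mpd(rng.choice(len(pool), size=len(focal), replace=False))
        for _ in range(reps)
    ])
    p = float(np.sum(null < observed) / reps)
    return MPDResult(observed, null, p)
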