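"""Trait-syndrome construction: rank-correlation PCA, exact two-group
discretization, and three-way strategy assignment.

Each syndrome (ecological specialization, r-K gradient, sexual dimorphism,
dispersal/social behaviour) is summarized by the first principal component of
a PCA on the Spearman rank-correlation matrix of its (disjoint) trait set.
Species are then split into ancestral (A) and derived (B) levels by the exact
optimum of one-dimensional 2-means clustering, i.e. the split maximizing the
between- over within-group variance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata, spearmanr
from sklearn.cluster import KMeans

__all__ = [
    "SyndromeDefinition",
    "SyndromeResult",
    "StrategyAssignment",
    "SpearmanPCA",
    "spearman_pca",
    "split_two_groups",
    "assign_strategies",
    "save_syndrome_definitions",
    "load_syndrome_definitions",
    "DegenerateVariableError",
]

SYNDROME_NAMES = (
    "ecological_specialization",
    "rK_gradient",
    "sexual_dimorphism",
    "dispersal_social",
)


class DegenerateVariableError(ValueError):
    """A constant column cannot be ranked/correlated."""


@dataclass
class SyndromeDefinition:
    """Which traits make up a syndrome, and which pole is 'derived'.

    derived_pole names the variables whose positive loading orients PC1, so
    higher scores mean the derived (B) end of the axis.
    """

    name: str
    variables: list[str]
    derived_pole: list[str] = field(default_factory=list)

    def __post_init__(self):
        unknown = set(self.derived_pole) - set(self.variables)
        if unknown:
            raise ValueError(f"derived_pole not within variables: {unknown}")


@dataclass
class SyndromeResult:
    """First-axis summary of one syndrome.

    scores : per-species PC1 coordinates (Series).
    loadings : Spearman correlation of each variable with the PC1 scores.
    eigenvalues : full spectrum of the rank-correlation matrix (descending).
    states : per-species 'A' (ancestral pole) / 'B' (derived pole) labels,
        filled in by :func:`split_two_groups`.
    """

    name: str
    scores: pd.Series
    loadings: pd.Series
    eigenvalues: np.ndarray
    species_axes: pd.DataFrame
    states: pd.Series | None = None

    @property
    def variance_fraction_pc1(self) -> float:
        return float(self.eigenvalues[0] / self.eigenvalues.sum())

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def summary(self) -> str:
        lines = [
            f"Syndrome PCA: {self.name}",
            "=" * 44,
            f"variables:        {len(self.loadings)}",
            f"PC1 variance:     {100 * self.variance_fraction_pc1:.1f}%",
            "PC1 loadings (Spearman r with scores):",
        ]
        for var, l in self.loadings.sort_values().items():
            lines.append(f"  {var}: {l:+.2f}")
        if self.states is not None:
            counts = self.states.value_counts()
            lines.append(
                f"states: A={counts.get('A', 0)}  B={counts.get('B', 0)}"
            )
        return "\n".join(lines)


class SpearmanPCA:
    """PCA on the Spearman rank-correlation matrix of a complete trait grid.

    Column ranks are standardized (population scaling) and projected onto the
    eigenvectors of the rank-correlation matrix, which keeps reported loadings
    equal to rank correlations between each variable and the axis scores.
    PC1 sign is oriented so the derived-pole variables load net-positive.
    """

    def __init__(self, data: pd.DataFrame, definition: SyndromeDefinition | None = None):
        if data.isna().any().any():
            raise ValueError("grid must be fully observed (impute first)")
        if data.shape[1] < 2 or data.shape[0] < 3:
            raise ValueError("need at least 3 species and 2 variables")
        constant = [c for c in data.columns if data[c].nunique() <= 1]
        if constant:
            raise DegenerateVariableError(
                f"constant variable(s) cannot be ranked: {constant}"
            )
        self.data = data
        self.definition = definition

    def fit(self) -> SyndromeResult:
        X = self.data.to_numpy(dtype=float)
        n, m = X.shape
        ranks = np.column_stack([rankdata(X[:, j]) for j in range(m)])
        Z = (ranks - ranks.mean(axis=0)) / ranks.std(axis=0)
        R = (Z.T @ Z) / n  # Spearman correlation matrix
        evals, evecs = np.linalg.eigh(R)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        scores = Z @ evecs
        # orientation: derived-pole variables load net-positive on PC1
        loadings1 = self._loadings(X, scores[:, 0])
        if self._flip(loadings1):
            evecs[:, 0] = -evecs[:, 0]
            scores[:, 0] = -scores[:, 0]
            loadings1 = -loadings1
        name = self.definition.name if self.definition else "syndrome"
        return SyndromeResult(
            name=name,
            scores=pd.Series(scores[:, 0], index=self.data.index, name="PC1"),
            loadings=pd.Series(loadings1, index=self.data.columns, name="PC1"),
            eigenvalues=np.clip(evals, 0.0, None),
            species_axes=pd.DataFrame(
                scores, index=self.data.index,
                columns=[f"PC{i + 1}" for i in range(m)],
            ),
        )

    def _loadings(self, X: np.ndarray, pc1: np.ndarray) -> np.ndarray:
        return np.array(
            [spearmanr(X[:, j], pc1).statistic for j in range(X.shape[1])]
        )

    def _flip(self, loadings: np.ndarray) -> bool:
        if self.definition and self.definition.derived_pole:
            pole_idx = [
                list(self.data.columns).index(v)
                for v in self.definition.derived_pole
                if v in self.data.columns
            ]
            if pole_idx:
                return loadings[pole_idx].sum() < 0
        return loadings[np.argmax(np.abs(loadings))] < 0


def spearman_pca(data: pd.DataFrame,
                 definition: SyndromeDefinition | None = None) -> SyndromeResult:
    """Convenience wrapper: fit a :class:`SpearmanPCA`."""
    return SpearmanPCA(data, definition).fit()


# ----------------------------------------------------------------------
def split_two_groups(scores) -> pd.Series:
    """Exact 1-D 2-means: scan all n-1 sorted breakpoints for the split
    minimizing within-group variance (equivalently maximizing the between/
    within variance ratio). Deterministic; the high-score group (the derived
    pole under the PC1 orientation convention) is labelled 'B'.
    """
    s = pd.Series(scores, dtype=float)
    x = s.to_numpy()
    if np.unique(x).size < 2:
        raise ValueError("cannot split constant scores")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    csum = np.cumsum(xs)
    csq = np.cumsum(xs ** 2)
    best_ss, best_i = np.inf, None
    for i in range(1, n):  # low group = xs[:i]
        if xs[i] == xs[i - 1]:
            continue  # identical values must stay together
        ss_lo = csq[i - 1] - csum[i - 1] ** 2 / i
        ss_hi = (csq[-1] - csq[i - 1]) - (csum[-1] - csum[i - 1]) ** 2 / (n - i)
        ss = ss_lo + ss_hi
        if ss < best_ss - 1e-15:
            best_ss, best_i = ss, i
    threshold = 0.5 * (xs[best_i - 1] + xs[best_i])
    labels = np.where(x > threshold, "B", "A")
    return pd.Series(labels, index=s.index, name="state")


# ----------------------------------------------------------------------
@dataclass
class StrategyAssignment:
    """Three-way strategy labels from k-means in the 3-D phylogenetic-PC
    space: A = ancestral cluster, B1 = derived cluster with the higher mean
    sexual-dimorphism score, B2 = the other derived cluster."""

    labels: pd.Series
    centroids: np.ndarray
    inertia: float

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(["A", "B1", "B2"], fill_value=0)


def assign_strategies(ppc_scores: pd.DataFrame,
                      ancestral_mask: pd.Series | None = None,
                      sex_scores: pd.Series | None = None,
                      k: int = 3, restarts: int = 100, seed: int = 0,
                      standardize: bool = False) -> StrategyAssignment:
    """Cluster species into k=3 strategies in the space of the first three
    phylogenetic-PC axes (best of `restarts` seeded k-means runs).

    Relabelling convention: the cluster holding the most species whose four
    binary syndrome states are all ancestral (`ancestral_mask` True) becomes
    A; of the remaining clusters, the one with the higher mean
    sexual-dimorphism score becomes B1 and the other B2. Without the optional
    inputs, clusters fall back to size (A = largest) and centroid-norm order.
    """
    X = ppc_scores.to_numpy(dtype=float)
    if X.shape[1] != 3:
        raise ValueError("expected exactly 3 phylogenetic-PC axes")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"fewer than {k} distinct points; k-means infeasible")
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(X)
    clusters = list(range(k))
    if ancestral_mask is not None:
        anc = ancestral_mask.reindex(ppc_scores.index).fillna(False).to_numpy()
        counts = [int(anc[raw == c].sum()) for c in clusters]
        a_cluster = int(np.argmax(counts))
    else:
        sizes = [int((raw == c).sum()) for c in clusters]
        a_cluster = int(np.argmax(sizes))
    rest = [c for c in clusters if c != a_cluster]
    if sex_scores is not None:
        sx = sex_scores.reindex(ppc_scores.index).to_numpy(dtype=float)
        means = [float(np.nanmean(sx[raw == c])) if (raw == c).any() else -np.inf
                 for c in rest]
        rest = [rest[int(np.argmax(means))], rest[int(np.argmin(means))]]
    else:
        norms = [float(np.linalg.norm(km.cluster_centers_[c])) for c in rest]
        rest = [rest[int(np.argmax(norms))], rest[int(np.argmin(norms))]]
    mapping = {a_cluster: "A", rest[0]: "B1", rest[1]: "B2"}
    labels = pd.Series([mapping[c] for c in raw], index=ppc_scores.index,
                       name="strategy")
    order = [a_cluster, rest[0], rest[1]]
    return StrategyAssignment(labels, km.cluster_centers_[order],
                              float(km.inertia_))


# ----------------------------------------------------------------------
def save_syndrome_definitions(definitions, path) -> None:
    """Write syndrome definitions as YAML (the format load_ reads back)."""
    payload = {d.name: {"variables": list(d.variables),
                        "derived_pole": list(d.derived_pole)}
               for d in definitions}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def load_syndrome_definitions(path) -> list[SyndromeDefinition]:
    """Read a YAML file mapping syndrome name -> {variables: [...],
    derived_pole: [...]}; enforces pairwise-disjoint variable sets."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    defs = [
        SyndromeDefinition(name, list(spec["variables"]),
                           list(spec.get("derived_pole", [])))
        for name, spec in raw.items()
    ]
    seen: set[str] = set()
    for d in defs:
        overlap = seen & set(d.variables)
        if overlap:
            raise ValueError(f"variables shared between syndromes: {overlap}")
        seen |= set(d.variables)
    return defs
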