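"""Mk continuous-time Markov models for discrete characters on phylogenies.

Implements the pruning (dynamic-programming) likelihood, maximum-likelihood
estimation of transition rates under arbitrary rate tying/zero constraints,
exact marginal ancestral-state reconstruction, and Pagel's correlated-evolution
likelihood-ratio test for pairs of binary characters.

The model: a character with k states evolves along each branch as a
continuous-time Markov chain with generator Q (off-diagonal entries are
nonnegative transition rates, rows sum to zero), so the transition kernel over
a branch of length t is expm(Q t). Tip observations may be hard states,
ambiguity vectors, or missing (treated as fully ambiguous). Rates are in
inverse units of the tree's branch lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

from .tree import Phylogeny

__all__ = [
    "RateModel",
    "MkModel",
    "MkResults",
    "PagelModel",
    "PagelResults",
    "transition_probabilities",
    "prune_log_likelihood",
    "fit_mk",
    "marginal_ancestral_states",
    "pagel_correlated_evolution",
    "DegenerateDataWarning",
]

RATE_MIN = 1e-8
RATE_MAX = 100.0


class DegenerateDataWarning(UserWarning):
    """Tip data carry no information about one or more rates."""


# ----------------------------------------------------------------------
@dataclass
class RateModel:
    """A k-state CTMC rate model.

    Parameters
    ----------
    states : ordered state labels.
    rates : (k, k) array of off-diagonal transition rates (diagonal ignored).
    constraint_mask : optional (k, k) boolean array; True marks free
        (estimable) off-diagonal entries, False marks entries fixed at their
        current value (typically 0). Defaults to all off-diagonal entries free.
    """

    states: tuple
    rates: np.ndarray
    constraint_mask: np.ndarray | None = None

    def __post_init__(self):
        self.states = tuple(self.states)
        self.rates = np.asarray(self.rates, dtype=float)
        k = len(self.states)
        if self.rates.shape != (k, k):
            raise ValueError("rates must be k x k")
        off = ~np.eye(k, dtype=bool)
        if np.any(self.rates[off] < 0):
            raise ValueError("transition rates must be nonnegative")
        if self.constraint_mask is None:
            self.constraint_mask = off.copy()
        else:
            self.constraint_mask = np.asarray(self.constraint_mask, dtype=bool)
            if self.constraint_mask.shape != (k, k):
                raise ValueError("constraint_mask must be k x k")
            self.constraint_mask &= off

    @property
    def k(self) -> int:
        return len(self.states)

    @property
    def generator(self) -> np.ndarray:
        q = self.rates.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def state_index(self, label) -> int:
        return self.states.index(label)


def transition_probabilities(model: RateModel | np.ndarray, t: float) -> np.ndarray:
    """Transition kernel P(t) = expm(Q t); closed form for two states."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    q = model.generator if isinstance(model, RateModel) else np.asarray(model, float)
    k = q.shape[0]
    if k == 2:
        return _propagators_2state(q, np.array([t]))[0]
    return expm(q * t)


def _propagators_2state(q: np.ndarray, tvec: np.ndarray) -> np.ndarray:
    a, b = q[0, 1], q[1, 0]
    s = a + b
    n = len(tvec)
    out = np.empty((n, 2, 2))
    if s == 0.0:
        out[:] = np.eye(2)
        return out
    e = np.exp(-s * tvec)
    pi0, pi1 = b / s, a / s
    out[:, 0, 0] = pi0 + pi1 * e
    out[:, 0, 1] = pi1 - pi1 * e
    out[:, 1, 0] = pi0 - pi0 * e
    out[:, 1, 1] = pi1 + pi0 * e
    return out


def _propagators(q: np.ndarray, tvec: np.ndarray) -> np.ndarray:
    """expm(Q t) for every t in tvec, shape (len(tvec), k, k).

    Uses the closed form for k=2 and an eigendecomposition for larger k,
    falling back to per-branch expm when Q is ill-conditioned.
    """
    k = q.shape[0]
    tvec = np.asarray(tvec, dtype=float)
    if k == 2:
        return _propagators_2state(q, tvec)
    try:
        d, u = np.linalg.eig(q)
        uinv = np.linalg.inv(u)
        if np.linalg.cond(u) < 1e8:
            ed = np.exp(np.multiply.outer(tvec, d))
            p = np.einsum("ik,nk,kj->nij", u, ed, uinv).real
            rows = p.sum(axis=2)
            if np.all(np.abs(rows - 1.0) < 1e-8) and p.min() > -1e-9:
                return np.clip(p, 0.0, 1.0)
    except np.linalg.LinAlgError:
        pass
    return np.array([expm(q * t) for t in tvec])


# ----------------------------------------------------------------------
def _tip_partial_matrix(tree: Phylogeny, tip_states, states) -> np.ndarray:
    """(n_nodes, k) conditional likelihood rows for tips; NaN/None/absent tips
    become all-ones ambiguity vectors (standard pruning convention)."""
    k = len(states)
    state_idx = {s: i for i, s in enumerate(states)}
    part = np.ones((tree.n_nodes, k))
    if isinstance(tip_states, pd.Series):
        tip_states = tip_states.to_dict()
    for label, val in tip_states.items():
        node = tree.tip_index(label)
        if val is None or (np.isscalar(val) and pd.isna(val)):
            continue
        if isinstance(val, (list, tuple, np.ndarray)):
            vec = np.asarray(val, dtype=float)
            if vec.shape != (k,):
                raise ValueError(f"ambiguity vector for {label!r} must have length {k}")
            part[node] = vec
        else:
            if val not in state_idx:
                raise ValueError(f"state {val!r} of tip {label!r} not in {states}")
            part[node] = 0.0
            part[node, state_idx[val]] = 1.0
    return part


def _root_prior_vector(policy, q: np.ndarray) -> np.ndarray:
    k = q.shape[0]
    if policy is None or policy == "uniform":
        return np.full(k, 1.0 / k)
    if policy == "stationary":
        # left null vector of Q
        w, v = np.linalg.eig(q.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.abs(v[:, i].real)
        return pi / pi.sum()
    vec = np.asarray(policy, dtype=float)
    if vec.shape != (k,) or vec.min() < 0 or not np.isclose(vec.sum(), 1.0):
        raise ValueError("root prior must be a probability vector of length k")
    return vec


def _binary_waves(tree: Phylogeny):
    """Group the internal nodes of a strictly binary tree into 'waves' such
    that within a wave both children are already computed, enabling a
    vectorized pruning pass. Returns None for trees with polytomies.
    Cached on the tree object."""
    cached = getattr(tree, "_wave_cache", False)
    if cached is not False:
        return cached
    waves = None
    if all(len(c) in (0, 2) for c in tree.children):
        level = np.zeros(tree.n_nodes, dtype=int)
        for i in tree.postorder():
            if tree.children[i]:
                c1, c2 = tree.children[i]
                level[i] = 1 + max(level[c1], level[c2])
        waves = []
        for lv in range(1, level.max() + 1):
            nodes = np.flatnonzero(level == lv)
            nodes = nodes[[bool(tree.children[i]) for i in nodes]]
            c1 = np.array([tree.children[i][0] for i in nodes], dtype=int)
            c2 = np.array([tree.children[i][1] for i in nodes], dtype=int)
            waves.append((nodes, c1, c2))
    tree._wave_cache = waves
    return waves


def _prune(tree: Phylogeny, q: np.ndarray, tip_partials: np.ndarray, root_prior: np.ndarray,
           return_messages: bool = False):
    """Felsenstein pruning with per-node rescaling.

    Returns (loglik,) or (loglik, inside, logscale, messages, pmats) when
    marginals are needed downstream. Binary trees take a vectorized path
    (level-grouped node waves); polytomies fall back to a per-node loop.
    """
    n = tree.n_nodes
    k = q.shape[0]
    pmats = _propagators(q, tree.blen)
    inside = np.empty((n, k))
    logscale = np.zeros(n)
    messages = np.empty((n, k)) if return_messages else None
    waves = _binary_waves(tree)
    bad = False
    if waves is not None:
        inside[tree.tip_indices] = tip_partials[tree.tip_indices]
        for nodes, c1, c2 in waves:
            m1 = np.einsum("nij,nj->ni", pmats[c1], inside[c1])
            m2 = np.einsum("nij,nj->ni", pmats[c2], inside[c2])
            if return_messages:
                messages[c1] = m1
                messages[c2] = m2
            v = m1 * m2
            mx = v.max(axis=1)
            if np.any(mx <= 0.0):
                bad = True
                break
            inside[nodes] = v / mx[:, None]
            logscale[nodes] = logscale[c1] + logscale[c2] + np.log(mx)
    else:
        for i in tree.postorder():
            kids = tree.children[i]
            if not kids:
                inside[i] = tip_partials[i]
                continue
            v = np.ones(k)
            ls = 0.0
            for c in kids:
                msg = pmats[c] @ inside[c]
                if return_messages:
                    messages[c] = msg
                v = v * msg
                ls += logscale[c]
            m = v.max()
            if m <= 0.0:
                bad = True
                break
            inside[i] = v / m
            logscale[i] = ls + np.log(m)
    if bad:
        return (-np.inf,) if not return_messages else (-np.inf, None, None, None, None)
    lik = float(root_prior @ inside[tree.root])
    ll = np.log(lik) + logscale[tree.root] if lik > 0 else -np.inf
    if return_messages:
        return ll, inside, logscale, messages, pmats
    return (ll,)


def prune_log_likelihood(tree: Phylogeny, tip_states, model: RateModel,
                         root_prior="uniform") -> float:
    """Log-likelihood of tip states under the Mk model, by pruning."""
    q = model.generator
    part = _tip_partial_matrix(tree, tip_states, model.states)
    prior = _root_prior_vector(root_prior, q)
    return _prune(tree, q, part, prior)[0]


def marginal_ancestral_states(tree: Phylogeny, tip_states, model: RateModel,
                              root_prior="uniform") -> pd.DataFrame:
    """Exact marginal posterior state probabilities for every node.

    Combines upward (inside) and downward (outside) partial likelihoods so
    each node's marginal conditions on all tip data. Rows are node names,
    columns are states; every row sums to 1.
    """
    q = model.generator
    k = model.k
    part = _tip_partial_matrix(tree, tip_states, model.states)
    prior = _root_prior_vector(root_prior, q)
    ll, inside, logscale, messages, pmats = _prune(
        tree, q, part, prior, return_messages=True
    )
    if not np.isfinite(ll):
        raise ValueError("data have zero likelihood under the model")
    outside = np.empty((tree.n_nodes, k))
    outside[tree.root] = prior
    for p in tree.preorder():
        kids = tree.children[p]
        if not kids:
            continue
        for c in kids:
            other = outside[p].copy()
            for b in kids:
                if b != c:
                    other = other * messages[b]
            vec = other @ pmats[c]
            s = vec.sum()
            outside[c] = vec / s if s > 0 else vec
    marg = inside * outside
    marg /= marg.sum(axis=1, keepdims=True)
    names = [tree.node_name(i) for i in range(tree.n_nodes)]
    return pd.DataFrame(marg, index=names, columns=list(model.states))


# ----------------------------------------------------------------------
def _fit_tied_rates(tree, tip_partials, param_map, root_prior_policy,
                    restarts, seed, fixed_rates=None, init_extra=None):
    """Maximize the pruning likelihood over tied log-rates.

    param_map: (k, k) int array; entry p >= 0 ties Q[i, j] to free parameter
    p, entry -1 marks a structural zero (or the diagonal). fixed_rates, if
    given, seeds structural nonzero fixed entries.
    """
    k = param_map.shape[0]
    n_par = int(param_map.max()) + 1
    base = np.zeros((k, k)) if fixed_rates is None else np.array(fixed_rates, float)

    def build_q(log_rates):
        q = base.copy()
        np.fill_diagonal(q, 0.0)
        rates = np.exp(log_rates)
        for p in range(n_par):
            q[param_map == p] = rates[p]
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def neg_ll(log_rates):
        q = build_q(log_rates)
        prior = _root_prior_vector(root_prior_policy, q)
        return -_prune(tree, q, tip_partials, prior)[0]

    rng = np.random.default_rng(seed)
    depth = tree.depths()[tree.tip_indices].mean()
    r0 = 1.0 / max(depth, 1e-6)
    inits = [np.full(n_par, np.log(r0))]
    if init_extra is not None:
        inits.append(np.clip(np.log(np.maximum(init_extra, RATE_MIN)),
                             np.log(RATE_MIN), np.log(RATE_MAX)))
    while len(inits) < restarts:
        inits.append(np.log(r0) + rng.uniform(-3.0, 3.0, size=n_par))
    bounds = [(np.log(RATE_MIN), np.log(RATE_MAX))] * n_par
    best = None
    for x0 in inits:
        res = minimize(neg_ll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    rates = np.exp(best.x)
    return build_q(best.x), rates, -float(best.fun), bool(best.success)


@dataclass
class MkResults:
    """ML fit of an Mk model: rates, log-likelihood and ancestral states."""

    model: RateModel
    log_likelihood: float
    root_prior: str | np.ndarray
    converged: bool
    n_restarts: int
    _tree: Phylogeny = field(repr=False)
    _tip_states: object = field(repr=False)

    @property
    def rates(self) -> np.ndarray:
        return self.model.rates

    @property
    def llf(self) -> float:
        return self.log_likelihood

    def ancestral_states(self) -> pd.DataFrame:
        """Marginal posterior state probabilities for every node (the data
        behind per-node pie charts)."""
        return marginal_ancestral_states(
            self._tree, self._tip_states, self.model, self.root_prior
        )

    @property
    def node_marginals(self) -> pd.DataFrame:
        return self.ancestral_states()

    @property
    def root_marginal(self) -> pd.Series:
        return self.ancestral_states().iloc[-1]

    def summary(self) -> str:
        lines = [
            "Mk model fit",
            "=" * 44,
            f"states:         {self.model.states}",
            f"log-likelihood: {self.log_likelihood:.6f}",
            f"root prior:     {self.root_prior}",
            f"converged:      {self.converged} ({self.n_restarts} restarts)",
            "transition rates (from -> to):",
        ]
        k = self.model.k
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                tag = "" if self.model.constraint_mask[i, j] else " (fixed)"
                lines.append(
                    f"  {self.model.states[i]} -> {self.model.states[j]}: "
                    f"{self.model.rates[i, j]:.6g}{tag}"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "states": list(map(str, self.model.states)),
            "rates": self.model.rates.tolist(),
            "log_likelihood": self.log_likelihood,
            "root_prior": (self.root_prior if isinstance(self.root_prior, str)
                           else list(self.root_prior)),
            "converged": self.converged,
        }


class MkModel:
    """Discrete-character Mk model for ML rate estimation on a fixed tree.

    Parameters
    ----------
    tree : Phylogeny with tips matching the keys of `tip_states`.
    tip_states : mapping or Series, species -> state label (or ambiguity
        vector / NaN for missing).
    states : optional explicit ordered state labels; inferred from the data
        when omitted.
    constraint_mask : optional (k, k) boolean array, True = free rate;
        entries with False are fixed at 0.
    root_prior : "uniform" (default), "stationary", or an explicit vector.
    """

    def __init__(self, tree: Phylogeny, tip_states, states=None,
                 constraint_mask=None, root_prior="uniform"):
        self.tree = tree
        if isinstance(tip_states, pd.Series):
            tip_states = tip_states.to_dict()
        self.tip_states = dict(tip_states)
        observed = sorted(
            {v for v in self.tip_states.values()
             if not (v is None or (np.isscalar(v) and pd.isna(v)))
             and not isinstance(v, (list, tuple, np.ndarray))},
            key=str,
        )
        self.states = tuple(states) if states is not None else tuple(observed)
        if len(self.states) < 2:
            raise ValueError("need at least two model states")
        self._observed = observed
        k = len(self.states)
        off = ~np.eye(k, dtype=bool)
        self.constraint_mask = (
            off if constraint_mask is None else np.asarray(constraint_mask, bool) & off
        )
        self.root_prior = root_prior
        self._partials = _tip_partial_matrix(tree, self.tip_states, self.states)

    def loglike(self, rates: np.ndarray) -> float:
        model = RateModel(self.states, rates, self.constraint_mask)
        q = model.generator
        prior = _root_prior_vector(self.root_prior, q)
        return _prune(self.tree, q, self._partials, prior)[0]

    def fit(self, restarts: int = 10, seed: int = 0) -> MkResults:
        k = len(self.states)
        if len(self._observed) < 2:
            warnings.warn(
                "all tips share one state; rates are at the lower boundary",
                DegenerateDataWarning,
            )
            rates = np.where(self.constraint_mask, RATE_MIN, 0.0)
            model = RateModel(self.states, rates, self.constraint_mask)
            ll = self.loglike(rates)
            return MkResults(model, ll, self.root_prior, True, 0,
                             self.tree, self.tip_states)
        param_map = np.full((k, k), -1, dtype=int)
        param_map[self.constraint_mask] = np.arange(int(self.constraint_mask.sum()))
        q, _, ll, ok = _fit_tied_rates(
            self.tree, self._partials, param_map, self.root_prior, restarts, seed
        )
        rates = q.copy()
        np.fill_diagonal(rates, 0.0)
        model = RateModel(self.states, rates, self.constraint_mask)
        return MkResults(model, ll, self.root_prior, ok, restarts,
                         self.tree, self.tip_states)


def fit_mk(tree, tip_states, states=None, constraint_mask=None,
           root_prior="uniform", restarts=10, seed=0) -> MkResults:
    """Convenience wrapper: build an :class:`MkModel` and fit it."""
    return MkModel(tree, tip_states, states=states,
                   constraint_mask=constraint_mask,
                   root_prior=root_prior).fit(restarts=restarts, seed=seed)


# ----------------------------------------------------------------------
# Pagel's correlated-evolution test on the 4-state product chain.
#
# Product states are ordered (x, y) = (0,0), (0,1), (1,0), (1,1); single-step
# transitions change exactly one character, simultaneous double transitions
# are structural zeros in both models.

_IND_PARAM_MAP = -np.ones((4, 4), dtype=int)
_IND_PARAM_MAP[0, 2] = _IND_PARAM_MAP[1, 3] = 0  # x: 0 -> 1
_IND_PARAM_MAP[2, 0] = _IND_PARAM_MAP[3, 1] = 1  # x: 1 -> 0
_IND_PARAM_MAP[0, 1] = _IND_PARAM_MAP[2, 3] = 2  # y: 0 -> 1
_IND_PARAM_MAP[1, 0] = _IND_PARAM_MAP[3, 2] = 3  # y: 1 -> 0

_DEP_PARAM_MAP = -np.ones((4, 4), dtype=int)
for _p, (_i, _j) in enumerate(
    [(0, 2), (1, 3), (2, 0), (3, 1), (0, 1), (2, 3), (1, 0), (3, 2)]
):
    _DEP_PARAM_MAP[_i, _j] = _p


@dataclass
class PagelResults:
    """Likelihood-ratio comparison of dependent vs independent evolution."""

    ll_independent: float
    ll_dependent: float
    df: int
    rates_independent: np.ndarray
    rates_dependent: np.ndarray
    states: tuple

    @property
    def lrt_statistic(self) -> float:
        return 2.0 * (self.ll_dependent - self.ll_independent)

    @property
    def p_value(self) -> float:
        return float(chi2.sf(max(self.lrt_statistic, 0.0), self.df))

    def summary(self) -> str:
        return "\n".join([
            "Pagel correlated-evolution test",
            "=" * 44,
            f"lnL independent (4 rates): {self.ll_independent:.6f}",
            f"lnL dependent   (8 rates): {self.ll_dependent:.6f}",
            f"LRT statistic:             {self.lrt_statistic:.6f}",
            f"df:                        {self.df}",
            f"p-value (chi-square):      {self.p_value:.9g}",
        ])

    def to_dict(self) -> dict:
        return {
            "ll_independent": self.ll_independent,
            "ll_dependent": self.ll_dependent,
            "lrt_statistic": self.lrt_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "rates_independent": self.rates_independent.tolist(),
            "rates_dependent": self.rates_dependent.tolist(),
        }


class PagelModel:
    """Correlated evolution of two binary characters on a shared tree.

    The independent model puts 4 free rates on the 4-state product chain
    (each character's gain/loss rate shared across the other character's
    state); the dependent model frees all 8 single-step rates. Simultaneous
    double transitions are forbidden in both. The LRT statistic
    2*(lnL_dep - lnL_indep) is referred to chi-square with df = 4.
    """

    def __init__(self, tree: Phylogeny, states_x, states_y, root_prior="uniform"):
        self.tree = tree
        self.root_prior = root_prior
        sx = pd.Series(states_x) if not isinstance(states_x, pd.Series) else states_x
        sy = pd.Series(states_y) if not isinstance(states_y, pd.Series) else states_y
        self._x01 = self._binarize(sx, "x")
        self._y01 = self._binarize(sy, "y")
        self.states = tuple(
            (a, b) for a in self._levels_x for b in self._levels_y
        )
        self._partials = self._product_partials()

    def _binarize(self, s: pd.Series, which: str) -> pd.Series:
        obs = s.dropna()
        levels = sorted(obs.unique(), key=str)
        if len(levels) != 2:
            raise ValueError(
                f"character {which} must have exactly two observed states, "
                f"got {levels}"
            )
        if which == "x":
            self._levels_x = tuple(levels)
        else:
            self._levels_y = tuple(levels)
        return s.map({levels[0]: 0, levels[1]: 1})

    def _product_partials(self) -> np.ndarray:
        part = np.ones((self.tree.n_nodes, 4))
        for label in self.tree.tip_labels:
            x = self._x01.get(label, np.nan)
            y = self._y01.get(label, np.nan)
            vx = np.ones(2) if pd.isna(x) else np.eye(2)[int(x)]
            vy = np.ones(2) if pd.isna(y) else np.eye(2)[int(y)]
            part[self.tree.tip_index(label)] = np.kron(vx, vy)
        return part

    def fit(self, restarts: int = 5, seed: int = 0) -> PagelResults:
        _, r_ind, ll_ind, _ = _fit_tied_rates(
            self.tree, self._partials, _IND_PARAM_MAP, self.root_prior,
            restarts, seed,
        )
        # nest the independent optimum into the dependent starts so
        # ll_dep >= ll_ind up to optimizer tolerance
        dep_start = np.array([r_ind[0], r_ind[0], r_ind[1], r_ind[1],
                              r_ind[2], r_ind[2], r_ind[3], r_ind[3]])
        _, r_dep, ll_dep, _ = _fit_tied_rates(
            self.tree, self._partials, _DEP_PARAM_MAP, self.root_prior,
            restarts, seed + 1, init_extra=dep_start,
        )
        return PagelResults(ll_ind, ll_dep, 4, r_ind, r_dep, self.states)


def pagel_correlated_evolution(tree, states_x, states_y, root_prior="uniform",
                               restarts=5, seed=0) -> PagelResults:
    """Fit independent and dependent product-chain models and return the LRT."""
    return PagelModel(tree, states_x, states_y, root_prior).fit(
        restarts=restarts, seed=seed
    )


# ----------------------------------------------------------------------
def profile_rate_intervals(model: MkModel, results: MkResults,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Profile-likelihood confidence intervals for each free rate.

    For each free rate the interval is the set of values at which the
    log-likelihood, re-maximized over the remaining free rates, stays within
    chi2(1, 1-alpha)/2 of the maximum. Boundary-limited intervals are clipped
    at the rate bounds.
    """
    drop = chi2.ppf(1.0 - alpha, 1) / 2.0
    k = len(model.states)
    free = [(i, j) for i in range(k) for j in range(k)
            if model.constraint_mask[i, j]]
    ll_max = results.log_likelihood
    target = ll_max - drop
    rates_ml = results.model.rates
    lo_b, hi_b = np.log(RATE_MIN), np.log(RATE_MAX)

    def profile_ll(entry, log_v):
        others = [e for e in free if e != entry]

        def neg(x):
            r = np.zeros((k, k))
            r[entry] = np.exp(log_v)
            for e, xv in zip(others, x):
                r[e] = np.exp(xv)
            return -model.loglike(r)

        if not others:
            return -neg([])
        x0 = np.array([np.log(max(rates_ml[e], RATE_MIN)) for e in others])
        res = minimize(neg, x0, method="L-BFGS-B",
                       bounds=[(lo_b, hi_b)] * len(others))
        return -res.fun

    def search(entry, direction):
        x_ml = np.log(max(rates_ml[entry], RATE_MIN))
        outer = lo_b if direction < 0 else hi_b
        if profile_ll(entry, outer) >= target:
            return np.exp(outer)
        a, b = (outer, x_ml) if direction < 0 else (x_ml, outer)
        for _ in range(30):
            m = 0.5 * (a + b)
            if profile_ll(entry, m) >= target:
                if direction < 0:
                    b = m
                else:
                    a = m
            else:
                if direction < 0:
                    a = m
                else:
                    b = m
            if b - a < 1e-3:
                break
        return np.exp(b if direction < 0 else a)

    rows = []
    for entry in free:
        i, j = entry
        rows.append({
            "from": str(model.states[i]),
            "to": str(model.states[j]),
            "rate": float(rates_ml[entry]),
            "ci_low": float(search(entry, -1)),
            "ci_high": float(search(entry, +1)),
        })
    return pd.DataFrame(rows)
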