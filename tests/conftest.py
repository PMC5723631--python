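import numpy as np
import pytest

from syndromevo import Phylogeny, simulate_yule_tree


@pytest.fixture
def worked_tree() -> Phylogeny:
    """Three-tip tree with hand-computable distances and proximities."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced4() -> Phylogeny:
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def yule81() -> Phylogeny:
    return simulate_yule_tree(81, 0.45, seed=11)


def brute_force_log_likelihood(tree, tip_states, model, root_prior=None):
    """Exhaustive sum over all internal-node state assignments (oracle for
    the pruning algorithm; exponential in node count, use on tiny trees)."""
    from itertools import product

    import scipy.linalg as sla

    k = model.k
    q = model.generator
    if root_prior is None:
        root_prior = np.full(k, 1.0 / k)
    pmats = [sla.expm(q * t) for t in tree.blen]
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    assign_tips = {}
    for l, s in tip_states.items():
        idx = model.states.index(s) if s in model.states else int(s)
        assign_tips[tree.tip_index(l)] = idx
    total = 0.0
    for combo in product(range(k), repeat=len(internal)):
        st = dict(zip(internal, combo))
        st.update(assign_tips)
        p = root_prior[st[tree.root]]
        for i in range(tree.n_nodes):
            if i != tree.root:
                p *= pmats[i][st[tree.parent[i]], st[i]]
        total += p
    return np.log(total)
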