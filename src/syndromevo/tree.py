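"""Rooted phylogenies with branch lengths, indexed for fast traversal.

Trees are parsed and serialized with dendropy but held internally as flat
postorder arrays (children lists, parent pointers, branch lengths), which is
what the pruning likelihood, simulators and distance computations operate on.
"""

from __future__ import annotations

import io
from typing import Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny"]


class Phylogeny:
    """A rooted tree with branch lengths and uniquely labelled tips.

    Nodes are indexed in postorder: every child precedes its parent and the
    root is the last node. ``blen[i]`` is the length of the branch above node
    ``i`` (0 for the root).

    Parameters
    ----------
    children : sequence of int lists, one per node (empty for tips).
    blen : branch length above each node; nonnegative.
    labels : tip label for each node (None for internal nodes unless named).
    """

    def __init__(self, children, blen, labels):
        self.children = [list(c) for c in children]
        self.blen = np.asarray(blen, dtype=float)
        self.labels = list(labels)
        n = len(self.children)
        if not (len(self.blen) == len(self.labels) == n):
            raise ValueError("children, blen and labels must have equal length")
        if np.any(self.blen < 0):
            raise ValueError("branch lengths must be nonnegative")
        self.parent = np.full(n, -1, dtype=int)
        for i, kids in enumerate(self.children):
            for c in kids:
                if c >= i:
                    raise ValueError("node indexing must be postorder")
                self.parent[c] = i
        self.tip_indices = np.array(
            [i for i, c in enumerate(self.children) if not c], dtype=int
        )
        self.tip_labels = [self.labels[i] for i in self.tip_indices]
        if any(lbl is None for lbl in self.tip_labels):
            raise ValueError("every tip must be labelled")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("tip labels must be unique")
        self._tip_index_of = {
            lbl: i for lbl, i in zip(self.tip_labels, self.tip_indices)
        }

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def tip_index(self, label: str) -> int:
        try:
            return self._tip_index_of[label]
        except KeyError:
            raise KeyError(f"tip {label!r} not in tree") from None

    def node_name(self, i: int) -> str:
        return self.labels[i] if self.labels[i] is not None else f"node{i}"

    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.seed_node.postorder_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        children, blen, labels = [], [], []
        for nd in nodes:
            children.append([index[id(c)] for c in nd.child_nodes()])
            blen.append(nd.edge.length if nd.edge.length is not None else 0.0)
            if nd.is_leaf():
                labels.append(nd.taxon.label if nd.taxon else nd.label)
            else:
                labels.append(nd.label)
        blen[-1] = 0.0  # root edge carries no information here
        return cls(children, blen, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(tree)

    @classmethod
    def read(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        buf = io.StringIO()

        def write(i: int):
            if self.is_tip(i):
                buf.write(self.labels[i])
            else:
                buf.write("(")
                for j, c in enumerate(self.children[i]):
                    if j:
                        buf.write(",")
                    write(c)
                buf.write(")")
                if self.labels[i] is not None:
                    buf.write(str(self.labels[i]))
            if i != self.root:
                buf.write(f":{self.blen[i]:.12g}")

        write(self.root)
        buf.write(";")
        return buf.getvalue()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------------
    def postorder(self) -> range:
        return range(self.n_nodes)

    def preorder(self):
        return range(self.n_nodes - 1, -1, -1)

    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n_nodes)
        for i in self.preorder():
            if i != self.root:
                d[i] = d[self.parent[i]] + self.blen[i]
        return d

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        td = self.depths()[self.tip_indices]
        return bool(np.ptp(td) <= tol)

    def total_length(self) -> float:
        return float(self.blen.sum())

    def path_to_root(self, i: int) -> list[int]:
        path = [i]
        while path[-1] != self.root:
            path.append(int(self.parent[path[-1]]))
        return path

    def mrca(self, i: int, j: int) -> int:
        anc = set(self.path_to_root(i))
        k = j
        while k not in anc:
            k = int(self.parent[k])
        return k

    def patristic_matrix(self, labels: Sequence[str] | None = None) -> np.ndarray:
        """Pairwise sum of branch lengths between tips, ordered as `labels`
        (defaults to ``tip_labels``)."""
        if labels is None:
            labels = self.tip_labels
        idx = [self.tip_index(l) for l in labels]
        depth = self.depths()
        n = len(idx)
        out = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                m = self.mrca(idx[a], idx[b])
                d = depth[idx[a]] + depth[idx[b]] - 2.0 * depth[m]
                out[a, b] = out[b, a] = d
        return out
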