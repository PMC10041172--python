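"""Greedy bottom-up reconstruction with maximum-parsimony root inference.

Starting from one singleton subtree per cell, the algorithm repeatedly joins
the pair of subtrees whose inferred roots share the most mutations and
replaces them with a new subtree whose root is the two-child
maximum-parsimony state under irreversible mutation from an unedited
ancestor: a character keeps a state only if both children agree on that
nonzero state, and is otherwise reset to unedited (0).  Its guarantee regime
assumes edge lengths bounded between l and c*l.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

from .topdown import _coerce_matrix, similarity_matrix
from .tree import LineageTree

__all__ = [
    "parsimony_root",
    "greedy_bottomup_reconstruct",
    "BottomUpReconstructor",
]


def parsimony_root(u, v) -> np.ndarray:
    """Two-child Fitch rule under irreversible mutations: per character, the
    shared nonzero state if both children agree, else unedited (0).

    Missing entries (-1) never match and therefore force 0.
    """
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError("state vectors must have equal length")
    return np.where((u == v) & (u > 0), u, 0)


def greedy_bottomup_reconstruct(X, leaf_names=None) -> LineageTree:
    """Iteratively join the two subtrees with the most similar roots.

    Ties are broken toward the lexicographically smallest pair of sorted
    member-label tuples, so reruns are deterministic.  Inferred internal
    state vectors are stored on the output tree nodes.
    """
    X, names = _coerce_matrix(X)
    if leaf_names is not None:
        if len(leaf_names) != X.shape[0]:
            raise ValueError("leaf_names length mismatch")
        names = sorted(str(x) for x in leaf_names)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty character matrix")
    g = nx.DiGraph()
    for i, name in enumerate(names):
        g.add_node(name, states=X[i].copy())
    if n == 1:
        return LineageTree(g, names[0])

    roots = [X[i].copy() for i in range(n)]     # inferred root states
    members = [(name,) for name in names]        # sorted member labels
    node_of = list(names)                        # tree node per active subtree
    S = similarity_matrix(X).astype(np.int64)
    np.fill_diagonal(S, -1)
    active = list(range(n))
    counter = itertools.count()

    while len(active) > 1:
        sub = S[np.ix_(active, active)]
        best = sub.max()
        ti, tj = np.nonzero(np.triu(sub == best, k=1))
        # deterministic tie-break on sorted member-label tuples
        cands = [(active[i], active[j]) for i, j in zip(ti, tj)]
        i, j = min(cands, key=lambda p: tuple(sorted((members[p[0]],
                                                      members[p[1]]))))
        new_root = parsimony_root(roots[i], roots[j])
        new_node = f"i{next(counter)}"
        g.add_node(new_node, states=new_root)
        g.add_edge(new_node, node_of[i], length=1.0)
        g.add_edge(new_node, node_of[j], length=1.0)
        # replace subtree i by the join, retire subtree j
        roots[i] = new_root
        members[i] = tuple(sorted(members[i] + members[j]))
        node_of[i] = new_node
        active.remove(j)
        row = ((np.asarray(roots) == new_root) & (new_root > 0)).sum(axis=1)
        S[i, :] = row
        S[:, i] = row
        S[i, i] = -1

    return LineageTree(g, node_of[active[0]])


class BottomUpReconstructor(BaseEstimator):
    """Greedy most-similar-roots joining reconstructor (parameter-free).

    After ``fit(X)`` the rooted topology is in ``tree_``; internal nodes
    carry their inferred maximum-parsimony state vectors.
    """

    def fit(self, X, y=None):
        self.tree_ = greedy_bottomup_reconstruct(X)
        self.leaf_names_ = self.tree_.leaves
        self.root_states_ = self.tree_.states(self.tree_.root)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).tree_
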