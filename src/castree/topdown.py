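"""Top-down reconstruction: the (l*, d*)-accurate partial triplet oracle and
the two oracle-driven algorithms.

The partial oracle compares shared-mutation counts inside a leaf triplet
against the threshold t = (1/2) k lam l* delta*(d*) (scaled by (1-p_d)^3 in
the worst-case missing-data mode).  Margins above t identify the outgroup;
otherwise the oracle abstains (``None``).  Reconstruction proceeds either by
recursive minimum-similarity edge deletion (threshold splitting) or by
feeding all resolved triplets to Aho's supertree algorithm.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from .model import LineageParams, delta_star
from .tree import LineageTree

__all__ = [
    "OracleConfig",
    "similarity",
    "similarity_matrix",
    "triplet_similarity_missing",
    "oracle_threshold",
    "partial_oracle",
    "threshold_split_reconstruct",
    "aho_supertree",
    "oracle_reconstruct",
    "ThresholdReconstructor",
    "OracleReconstructor",
]


# --------------------------------------------------------------- similarities
def similarity(a, b) -> int:
    """Number of positions where a and b share the same nonzero, nonmissing
    state (the shared-mutation count s(a, b))."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("state vectors must have equal length")
    return int(np.sum((a == b) & (a > 0)))


def similarity_matrix(X) -> np.ndarray:
    """All pairwise shared-mutation counts; symmetric, diagonal = number of
    mutated entries of each row."""
    X = np.asarray(X)
    n = X.shape[0]
    S = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        S[i] = ((X == X[i]) & (X[i] > 0)).sum(axis=1)
    return S


def triplet_similarity_missing(a, b, c):
    """Pairwise shared-mutation counts over the characters with no dropout in
    *any* of a, b, c.  Returns (s(a,b), s(a,c), s(b,c))."""
    a, b, c = (np.asarray(x) for x in (a, b, c))
    ok = (a >= 0) & (b >= 0) & (c >= 0)
    s_ab = int(np.sum(ok & (a == b) & (a > 0)))
    s_ac = int(np.sum(ok & (a == c) & (a > 0)))
    s_bc = int(np.sum(ok & (b == c) & (b > 0)))
    return s_ab, s_ac, s_bc


# --------------------------------------------------------------------- oracle
@dataclass(frozen=True)
class OracleConfig:
    """Tolerances of the partial oracle.

    ``l_star`` (separation) and ``d_star`` (depth) define which triplets the
    oracle must resolve; ``zeta`` is the failure budget used by the
    character-count bounds; ``missing_mode='worst_case'`` switches to the
    triplet-conditioned similarity and scales the threshold by (1-p_d)^3.
    ``threshold_t``, if given, overrides the derived threshold.
    """

    l_star: float
    d_star: float = 1.0
    zeta: float = 0.1
    missing_mode: str = "none"
    p_d: float = 0.0
    threshold_t: float = None

    def __post_init__(self):
        if self.l_star <= 0:
            raise ValueError("l_star must be positive")
        if not (0.0 <= self.d_star <= 1.0):
            raise ValueError("d_star must be in [0, 1]")
        if self.missing_mode not in ("none", "worst_case"):
            raise ValueError(f"unknown missing_mode {self.missing_mode!r}")
        if not (0.0 <= self.p_d < 1.0):
            raise ValueError("p_d must be in [0, 1)")


def oracle_threshold(k: int, lam: float, q: float, cfg: OracleConfig) -> float:
    """Decision threshold t = (1/2) k lam l* delta*(d*), times (1-p_d)^3 in
    the worst-case missing-data mode."""
    if cfg.threshold_t is not None:
        return float(cfg.threshold_t)
    if lam * cfg.l_star > 1.0 + 1e-12:
        warnings.warn(
            f"lam * l_star = {lam * cfg.l_star:.3g} > 1; the oracle guarantees "
            "assume lam * l_star <= 1", stacklevel=2)
    t = 0.5 * k * lam * cfg.l_star * delta_star(cfg.d_star, lam, q)
    if cfg.missing_mode == "worst_case":
        t *= (1.0 - cfg.p_d) ** 3
    return float(t)


def partial_oracle(a, b, c, cfg: OracleConfig, params: LineageParams):
    """Query the partial oracle on three leaf state vectors.

    Returns the index (0, 1, 2) of the outgroup among (a, b, c), or ``None``
    when no pairwise margin exceeds the threshold.
    """
    t = oracle_threshold(params.k, params.lam, params.collision_q, cfg)
    if cfg.missing_mode == "worst_case":
        s_ab, s_ac, s_bc = triplet_similarity_missing(a, b, c)
    else:
        s_ab, s_ac, s_bc = similarity(a, b), similarity(a, c), similarity(b, c)
    margins = (
        s_bc - max(s_ab, s_ac),  # a is the outgroup
        s_ac - max(s_ab, s_bc),  # b is the outgroup
        s_ab - max(s_ac, s_bc),  # c is the outgroup
    )
    hits = [i for i, m in enumerate(margins) if m > t]
    assert len(hits) <= 1, "two margins cannot both exceed a nonnegative threshold"
    return hits[0] if hits else None


# ----------------------------------------------------------------- coercion
def _coerce_matrix(X):
    """Accept a DataFrame (index = cell ids) or array; return (array, names)
    with rows sorted by cell label for reproducibility."""
    if isinstance(X, pd.DataFrame):
        names = [str(i) for i in X.index]
        values = X.to_numpy()
    else:
        values = np.asarray(X)
        if values.ndim != 2:
            raise ValueError("character matrix must be 2-dimensional")
        width = max(1, len(str(max(values.shape[0] - 1, 0))))
        names = [f"c{i:0{width}d}" for i in range(values.shape[0])]
    if len(set(names)) != len(names):
        raise ValueError("duplicate cell ids")
    order = np.argsort(np.asarray(names, dtype=object))
    return values[order].astype(np.int64, copy=False), [names[i] for i in order]


# ------------------------------------------------------- threshold splitting
def threshold_split_reconstruct(X, leaf_names=None) -> LineageTree:
    """Recursive minimum-similarity edge deletion.

    At each call the complete similarity-weighted graph over the current
    cells has its globally minimum-weight edges (all ties at once) deleted
    until it disconnects; the components become child subproblems.  Per-call
    cost is O(k |V|^2) for the similarity computation.
    """
    X, names = _coerce_matrix(X)
    if leaf_names is not None:
        if len(leaf_names) != X.shape[0]:
            raise ValueError("leaf_names length mismatch")
        names = sorted(str(x) for x in leaf_names)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty character matrix")
    S = similarity_matrix(X)
    g = nx.DiGraph()
    counter = itertools.count()
    if n == 1:
        g.add_node(names[0])
        return LineageTree(g, names[0])

    def build(idx: np.ndarray) -> str:
        if idx.size == 1:
            return names[idx[0]]
        node = f"i{next(counter)}"
        if idx.size == 2:
            for i in idx:
                g.add_edge(node, names[i], length=1.0)
            return node
        sub = S[np.ix_(idx, idx)]
        weights = np.unique(sub[np.triu_indices(idx.size, 1)])
        for w in weights:
            adj = sub > w
            np.fill_diagonal(adj, False)
            ncomp, labels = connected_components(csr_matrix(adj),
                                                 directed=False)
            if ncomp > 1:
                break
        for comp in range(ncomp):
            child = build(idx[labels == comp])
            g.add_edge(node, child, length=1.0)
        return node

    root = build(np.arange(n))
    return LineageTree(g, root)


# --------------------------------------------------------------- Aho supertree
def aho_supertree(triplets, labels) -> LineageTree:
    """Aho's recursive connected-components supertree.

    ``triplets`` is an iterable of (a, b, c) meaning (a, b | c).  Within the
    current label set, an edge {a, b} is added for every triplet whose three
    members are all present; each connected component is recursed on and the
    results joined under a new root.  A connected component that never splits
    (irreducible constraint set) becomes a single multifurcating node, so the
    algorithm is total.
    """
    labels = sorted(str(x) for x in labels)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    trips = [(str(a), str(b), str(c)) for a, b, c in triplets]
    for a, b, c in trips:
        for x in (a, b, c):
            if x not in set(labels):
                raise ValueError(f"triplet label {x!r} not in leaf set")
    g = nx.DiGraph()
    counter = itertools.count()
    if len(labels) == 1:
        g.add_node(labels[0])
        return LineageTree(g, labels[0])

    def build(labs: list, trips: list) -> str:
        if len(labs) == 1:
            return labs[0]
        node = f"i{next(counter)}"
        if len(labs) == 2:
            for x in labs:
                g.add_edge(node, x, length=1.0)
            return node
        h = nx.Graph()
        h.add_nodes_from(labs)
        members = set(labs)
        active = [t for t in trips if t[0] in members and t[1] in members
                  and t[2] in members]
        h.add_edges_from((a, b) for a, b, _ in active)
        comps = sorted(nx.connected_components(h), key=min)
        if len(comps) == 1:
            # irreducible: emit a multifurcation over the members
            for x in labs:
                g.add_edge(node, x, length=1.0)
            return node
        for comp in comps:
            child = build(sorted(comp), active)
            g.add_edge(node, child, length=1.0)
        return node

    root = build(labels, trips)
    return LineageTree(g, root)


# ------------------------------------------------------ oracle reconstruction
def _resolved_triplets(X, names, t, missing_mode, chunk=2048):
    """Vectorized oracle query over all C(n,3) triplets (lexicographic)."""
    n = X.shape[0]
    combos = np.array(list(itertools.combinations(range(n), 3)), dtype=np.int64)
    if combos.size == 0:
        return []
    out = []
    if missing_mode == "none" or not np.any(X < 0):
        S = similarity_matrix(X)
        ia, ib, ic = combos.T
        s_ab, s_ac, s_bc = S[ia, ib], S[ia, ic], S[ib, ic]
        out.append((ia, ib, ic, s_ab, s_ac, s_bc))
    else:
        for start in range(0, combos.shape[0], chunk):
            ia, ib, ic = combos[start:start + chunk].T
            A, B, C = X[ia], X[ib], X[ic]
            ok = (A >= 0) & (B >= 0) & (C >= 0)
            s_ab = (ok & (A == B) & (A > 0)).sum(axis=1)
            s_ac = (ok & (A == C) & (A > 0)).sum(axis=1)
            s_bc = (ok & (B == C) & (B > 0)).sum(axis=1)
            out.append((ia, ib, ic, s_ab, s_ac, s_bc))
    triplets = []
    for ia, ib, ic, s_ab, s_ac, s_bc in out:
        m_a = s_bc - np.maximum(s_ab, s_ac)  # a outgroup
        m_b = s_ac - np.maximum(s_ab, s_bc)  # b outgroup
        m_c = s_ab - np.maximum(s_ac, s_bc)  # c outgroup
        for sel, ing1, ing2, outg in ((m_a, ib, ic, ia), (m_b, ia, ic, ib),
                                      (m_c, ia, ib, ic)):
            for j in np.nonzero(sel > t)[0]:
                triplets.append((names[ing1[j]], names[ing2[j]],
                                 names[outg[j]]))
    return triplets


def oracle_reconstruct(X, cfg: OracleConfig, params: LineageParams,
                       leaf_names=None) -> LineageTree:
    """Query the partial oracle on every leaf triplet and assemble the
    non-Null answers with Aho's supertree algorithm."""
    X, names = _coerce_matrix(X)
    if leaf_names is not None:
        names = sorted(str(x) for x in leaf_names)
    t = oracle_threshold(params.k, params.lam, params.collision_q, cfg)
    triplets = _resolved_triplets(X, names, t, cfg.missing_mode)
    return aho_supertree(triplets, names)


# ------------------------------------------------------------------ estimators
class ThresholdReconstructor(BaseEstimator):
    """Recursive minimum-similarity splitting reconstructor.

    Parameter-free: the splits depend only on the shared-mutation counts.
    After ``fit(X)`` the rooted topology over the input cells is in
    ``tree_`` and the cell labels in ``leaf_names_``.
    """

    def fit(self, X, y=None):
        self.tree_ = threshold_split_reconstruct(X)
        self.leaf_names_ = self.tree_.leaves
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).tree_


class OracleReconstructor(BaseEstimator):
    """Partial-oracle + Aho supertree reconstructor.

    Parameters mirror the oracle's tolerances and the generative rates the
    threshold depends on: ``lam`` (mutation rate), ``q`` (state-collision
    probability), ``l_star``, ``d_star``, ``p_d`` and ``missing_mode``.
    """

    def __init__(self, lam=1.0, q=0.1, l_star=0.05, d_star=1.0,
                 p_d=0.0, missing_mode="none"):
        self.lam = lam
        self.q = q
        self.l_star = l_star
        self.d_star = d_star
        self.p_d = p_d
        self.missing_mode = missing_mode

    def fit(self, X, y=None):
        Xv, names = _coerce_matrix(X)
        cfg = OracleConfig(l_star=self.l_star, d_star=self.d_star,
                           missing_mode=self.missing_mode, p_d=self.p_d)
        t = oracle_threshold(Xv.shape[1], self.lam, self.q, cfg)
        self.threshold_ = t
        triplets = _resolved_triplets(Xv, names, t, cfg.missing_mode)
        self.n_resolved_ = len(triplets)
        self.tree_ = aho_supertree(triplets, names)
        self.leaf_names_ = names
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).tree_
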