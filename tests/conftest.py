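"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from castree.tree import LineageTree


# --------------------------------------------------------------- tree builders
def random_binary_tree(n: int, rng, unit_lengths: bool = True) -> LineageTree:
    """Random rooted binary tree over leaves l0..l{n-1} by random joins."""
    g = nx.DiGraph()
    active = [f"l{i}" for i in range(n)]
    g.add_nodes_from(active)
    counter = itertools.count()
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        node = f"v{next(counter)}"
        length_i = 1.0 if unit_lengths else float(rng.uniform(0.1, 1.0))
        length_j = 1.0 if unit_lengths else float(rng.uniform(0.1, 1.0))
        g.add_edge(node, active[i], length=length_i)
        g.add_edge(node, active[j], length=length_j)
        active = [a for k, a in enumerate(active) if k not in (i, j)] + [node]
    return LineageTree(g, active[0])


def triplet_tree(d: float, l_prime: float) -> LineageTree:
    """Height-1 tree realizing triplet geometry (a, b | c): LCA(a,b,c) at
    depth d, ingroup ancestor a further l_prime below it."""
    g = nx.DiGraph()
    g.add_edge("r", "u", length=d)
    g.add_edge("u", "c", length=1.0 - d)
    g.add_edge("u", "v", length=l_prime)
    g.add_edge("v", "a", length=1.0 - d - l_prime)
    g.add_edge("v", "b", length=1.0 - d - l_prime)
    return LineageTree(g, "r")


# --------------------------------------------------- independent triplet oracle
def root_path(tree: LineageTree, v) -> list:
    path = [v]
    while True:
        preds = list(tree.graph.predecessors(path[-1]))
        if not preds:
            break
        path.append(preds[0])
    return path[::-1]


def brute_lca_depth(tree: LineageTree, u, v):
    """(branch-length depth, edge-count depth) of LCA(u, v) via root paths."""
    pu, pv = root_path(tree, u), root_path(tree, v)
    depth_len, depth_cnt, w = 0.0, 0, pu[0]
    for x, y in zip(pu[1:], pv[1:]):
        if x != y:
            break
        depth_len += tree.edge_length(w, x)
        depth_cnt += 1
        w = x
    return depth_len, depth_cnt


def brute_outgroup(tree: LineageTree, a, b, c):
    """Outgroup of the triplet by direct LCA comparison; None if a polytomy."""
    dab = brute_lca_depth(tree, a, b)[1]
    dac = brute_lca_depth(tree, a, c)[1]
    dbc = brute_lca_depth(tree, b, c)[1]
    if dab > dac and dab > dbc:
        return c
    if dac > dab and dac > dbc:
        return b
    if dbc > dab and dbc > dac:
        return a
    return None


def brute_triplets_correct(true_tree, inferred_tree, depth_limit=1.0):
    """Exhaustive per-triplet recount of the triplet accuracy metric."""
    n_total = n_correct = 0
    for a, b, c in itertools.combinations(true_tree.leaves, 3):
        lca_depth = min(brute_lca_depth(true_tree, x, y)[0]
                        for x, y in itertools.combinations((a, b, c), 2))
        if lca_depth > depth_limit + 1e-9:
            continue
        n_total += 1
        out_t = brute_outgroup(true_tree, a, b, c)
        out_i = brute_outgroup(inferred_tree, a, b, c)
        if out_t is not None and out_t == out_i:
            n_correct += 1
    return n_correct, n_total


def all_triplets(tree: LineageTree) -> list:
    """Every resolved triplet (in1, in2, out) of a tree, by brute force."""
    trips = []
    for a, b, c in itertools.combinations(tree.leaves, 3):
        out = brute_outgroup(tree, a, b, c)
        if out is not None:
            ing = [x for x in (a, b, c) if x != out]
            trips.append((ing[0], ing[1], out))
    return trips


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
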