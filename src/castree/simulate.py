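"""Forward-time simulation of lineage-tracing experiments.

Two topology regimes are provided:

* ``uniform`` — a complete binary tree (regular molecular clock) of
  ``n = 2^h`` leaves under an implicit root, every edge of length
  ``1 / (log2(n) + 1)`` so the tree has height exactly 1.
* ``asynchronous`` — a forward-time Bellman-Harris branching process with
  extinction: division waiting times are exponential shifted by a constant
  ``a`` (the minimum time between divisions) and death waiting times are
  exponential.  All lineages stop at time 1; trees are rejection-sampled
  until the leaf count falls in a configured window.

Character states are then overlaid edge-by-edge: an unedited character
mutates on an edge of length t with probability 1 - e^{-lam t}, adopts
state j with probability q_j, and keeps that state in all descendants
(irreversibility).  Missing data can be stochastic (independent per leaf
entry) or heritable (an event on an edge masks the character in the whole
descendant clade).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .model import LineageParams
from .tree import LineageTree

__all__ = [
    "TopologyConfig",
    "simulate_uniform_topology",
    "simulate_async_topology",
    "sample_division_waiting_times",
    "overlay_mutations",
    "apply_stochastic_dropout",
    "apply_heritable_dropout",
    "extract_character_matrix",
    "simulate_experiment",
    "as_rng",
]


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TopologyConfig:
    """Configuration of the cell-division topology simulation.

    ``birth_rate`` is the rate of the exponential part of the division
    waiting time (total wait = shift_a + Exp(birth_rate)); ``death_rate``
    the rate of the exponential death waiting time (0 disables death).
    Defaults target the asynchronous acceptance window of 205-307 leaves
    at time 1.
    """

    regime: str = "uniform"
    n_target: int = 256
    n_min: int = 205
    n_max: int = 307
    shift_a: float = 0.05
    birth_rate: float = 13.0
    death_rate: float = 0.3
    max_retries: int = 10_000

    def __post_init__(self):
        if self.regime not in ("uniform", "asynchronous"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "uniform":
            n = self.n_target
            if n < 1 or (n & (n - 1)) != 0:
                raise ValueError(f"uniform regime needs a power-of-two leaf "
                                 f"count, got {n}")
        if self.shift_a < 0:
            raise ValueError("shift_a must be nonnegative")
        if self.n_min > self.n_max:
            raise ValueError("empty leaf-count acceptance window")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if self.death_rate < 0:
            raise ValueError("death_rate must be nonnegative")


def _leaf_name(i: int, n: int) -> str:
    width = max(1, len(str(n - 1)))
    return f"c{i:0{width}d}"


def simulate_uniform_topology(n_target: int) -> LineageTree:
    """Complete binary tree of ``n_target = 2^h`` leaves plus an implicit
    root, every edge of length 1/(log2(n) + 1)."""
    n = int(n_target)
    if n < 1 or (n & (n - 1)) != 0:
        raise ValueError(f"n_target must be a power of two, got {n_target}")
    h = n.bit_length() - 1  # log2(n)
    length = 1.0 / (h + 1)
    g = nx.DiGraph()
    g.add_edge("root", "i0", length=length)
    # complete binary tree below i0, breadth-first labels
    frontier = ["i0"]
    counter = itertools.count(1)
    for _ in range(h):
        nxt = []
        for v in frontier:
            for _ in range(2):
                c = f"i{next(counter)}"
                g.add_edge(v, c, length=length)
                nxt.append(c)
        frontier = nxt
    if h == 0:
        frontier = ["i0"]
    mapping = {v: _leaf_name(i, n) for i, v in enumerate(frontier)}
    g = nx.relabel_nodes(g, mapping)
    return LineageTree(g, "root")


def sample_division_waiting_times(cfg: TopologyConfig, size: int,
                                  rng=None) -> np.ndarray:
    """Draw division waiting times: shift_a + Exp(birth_rate)."""
    rng = as_rng(rng)
    return cfg.shift_a + rng.exponential(1.0 / cfg.birth_rate, size=size)


def _grow_bellman_harris(cfg: TopologyConfig, rng) -> nx.DiGraph | None:
    """One forward pass; returns the pruned tree graph or None on extinction."""
    g = nx.DiGraph()
    g.add_node("root", time=0.0)
    counter = itertools.count()
    # stack of (parent node, birth time of this lineage)
    stack = [("root", 0.0)]
    while stack:
        parent, t0 = stack.pop()
        wait_div = cfg.shift_a + rng.exponential(1.0 / cfg.birth_rate)
        wait_death = (rng.exponential(1.0 / cfg.death_rate)
                      if cfg.death_rate > 0 else np.inf)
        if t0 + min(wait_div, wait_death) >= 1.0:
            v = f"L{next(counter)}"
            g.add_node(v, time=1.0)
            g.add_edge(parent, v, length=1.0 - t0)
        elif wait_death < wait_div:
            continue  # lineage dies before dividing; leaves nothing
        else:
            t1 = t0 + wait_div
            v = f"D{next(counter)}"
            g.add_node(v, time=t1)
            g.add_edge(parent, v, length=wait_div)
            stack.append((v, t1))
            stack.append((v, t1))
    # prune subtrees with no surviving (time-1) leaf
    alive = {v for v in g.nodes if g.out_degree(v) == 0 and
             g.nodes[v]["time"] >= 1.0}
    if not alive:
        return None
    keep = set(alive)
    for v in alive:
        keep.update(nx.ancestors(g, v))
    g = g.subgraph(keep).copy()
    # suppress unifurcations (a division whose sibling clade died)
    for v in list(g.nodes):
        if v == "root":
            continue
        if g.out_degree(v) == 1 and g.in_degree(v) == 1:
            (p,) = g.predecessors(v)
            (c,) = g.successors(v)
            g.add_edge(p, c, length=g.edges[p, v]["length"] +
                       g.edges[v, c]["length"])
            g.remove_node(v)
    return g


def simulate_async_topology(cfg: TopologyConfig, rng=None) -> LineageTree:
    """Bellman-Harris topology, rejection-sampled into [n_min, n_max] leaves.

    Every accepted tree is ultrametric of height 1, carries the implicit-root
    edge, and every division waiting time is at least ``cfg.shift_a``.
    """
    rng = as_rng(rng)
    for _ in range(cfg.max_retries):
        g = _grow_bellman_harris(cfg, rng)
        if g is None:
            continue
        n = sum(1 for v in g.nodes if g.out_degree(v) == 0)
        if cfg.n_min <= n <= cfg.n_max:
            # deterministic relabeling: leaves in DFS order
            leaves = [v for v in nx.dfs_preorder_nodes(g, "root")
                      if g.out_degree(v) == 0]
            mapping = {v: _leaf_name(i, n) for i, v in enumerate(leaves)}
            internal = itertools.count()
            for v in nx.dfs_preorder_nodes(g, "root"):
                if v != "root" and g.out_degree(v) > 0:
                    mapping[v] = f"i{next(internal)}"
            return LineageTree(nx.relabel_nodes(g, mapping), "root")
    raise RuntimeError(
        f"no tree with {cfg.n_min}-{cfg.n_max} leaves in "
        f"{cfg.max_retries} attempts; recalibrate birth/death rates"
    )


def simulate_topology(cfg: TopologyConfig, rng=None) -> LineageTree:
    if cfg.regime == "uniform":
        return simulate_uniform_topology(cfg.n_target)
    return simulate_async_topology(cfg, rng)


def overlay_mutations(tree: LineageTree, params: LineageParams,
                      rng=None) -> LineageTree:
    """Overlay the irreversible Cas9 mutation process on ``tree``.

    Returns a copy whose every node carries a ``states`` vector of length
    ``params.k``; the root is all-zero and a character, once mutated, keeps
    its state in all descendants.
    """
    rng = as_rng(rng)
    tree = tree.copy()
    g = tree.graph
    k, lam, m = params.k, params.lam, params.m
    g.nodes[tree.root]["states"] = np.zeros(k, dtype=np.int64)
    for u, v in nx.dfs_edges(g, tree.root):
        t = tree.edge_length(u, v)
        parent_states = g.nodes[u]["states"]
        child = parent_states.copy()
        editable = child == 0
        p_mut = -np.expm1(-lam * t)  # lam = 0 gives the no-editing control
        hit = editable & (rng.random(k) < p_mut)
        n_hit = int(hit.sum())
        if n_hit:
            child[hit] = rng.choice(np.arange(1, m + 1), size=n_hit,
                                    p=params.state_probs)
        g.nodes[v]["states"] = child
    return tree


def apply_stochastic_dropout(matrix, p_d: float, rng=None):
    """Independently mask each entry with probability ``p_d`` (sentinel -1)."""
    if not (0.0 <= p_d <= 1.0):
        raise ValueError(f"p_d must be in [0, 1], got {p_d}")
    rng = as_rng(rng)
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    masked = values.copy()
    masked[rng.random(values.shape) < p_d] = -1
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(masked, index=matrix.index, columns=matrix.columns)
    return masked


def apply_heritable_dropout(tree: LineageTree, rate: float,
                            rng=None) -> LineageTree:
    """Place heritable dropout events (resection / silencing) on edges.

    Independently per character, an event occurs on an edge of length t with
    probability 1 - e^{-rate t} and masks that character in the entire
    descendant clade.  The mask is stored per node as ``dropout_mask`` and
    applied when the character matrix is extracted.
    """
    if rate < 0:
        raise ValueError("dropout rate must be nonnegative")
    rng = as_rng(rng)
    tree = tree.copy()
    g = tree.graph
    k = g.nodes[tree.root]["states"].size
    g.nodes[tree.root]["dropout_mask"] = np.zeros(k, dtype=bool)
    for u, v in nx.dfs_edges(g, tree.root):
        t = tree.edge_length(u, v)
        p = -np.expm1(-rate * t) if rate > 0 else 0.0
        events = rng.random(k) < p
        g.nodes[v]["dropout_mask"] = g.nodes[u]["dropout_mask"] | events
    return tree


def extract_character_matrix(tree: LineageTree) -> pd.DataFrame:
    """Leaf character matrix (rows ordered by leaf label), -1 where masked."""
    if not tree.has_states():
        raise ValueError("tree carries no character states; run "
                         "overlay_mutations first")
    rows = []
    for leaf in tree.leaves:
        states = tree.states(leaf).copy()
        mask = tree.graph.nodes[leaf].get("dropout_mask")
        if mask is not None:
            states[mask] = -1
        rows.append(states)
    k = rows[0].size
    return pd.DataFrame(np.vstack(rows), index=tree.leaves,
                        columns=[f"r{j}" for j in range(k)])


def heritable_rate_for_total(p_d: float, fraction_heritable: float) -> tuple:
    """Split a total per-leaf missing probability ``p_d`` into a heritable
    event rate and a residual stochastic probability.

    A heritable rate h gives per-leaf masking probability 1 - e^{-h} on a
    height-1 tree; the stochastic component then fills up to ``p_d``:
    (1 - p_h)(1 - p_s) = 1 - p_d.
    """
    if not (0 <= fraction_heritable <= 1):
        raise ValueError("fraction_heritable must be in [0, 1]")
    p_h = p_d * fraction_heritable
    rate = -np.log1p(-p_h)
    p_s = 1.0 - (1.0 - p_d) / (1.0 - p_h) if p_h < 1 else 0.0
    return float(rate), float(p_s)


def simulate_experiment(params: LineageParams, topo_cfg: TopologyConfig,
                        rng=None, tree: LineageTree = None,
                        heritable_fraction: float = 0.0):
    """Run one full experiment: topology -> mutations -> dropout.

    Returns ``(ground_truth_tree, character_matrix)``; the tree keeps the
    unmasked internal states.  ``tree`` may be supplied to reuse a topology
    (the uniform-regime replicate design overlays several mutation datasets
    on one topology).
    """
    rng = as_rng(rng)
    if tree is None:
        tree = simulate_topology(topo_cfg, rng)
    mutated = overlay_mutations(tree, params, rng)
    if params.p_d > 0 and heritable_fraction > 0:
        rate, p_s = heritable_rate_for_total(params.p_d, heritable_fraction)
        mutated = apply_heritable_dropout(mutated, rate, rng)
        matrix = extract_character_matrix(mutated)
        matrix = apply_stochastic_dropout(matrix, p_s, rng)
    else:
        matrix = extract_character_matrix(mutated)
        if params.p_d > 0:
            matrix = apply_stochastic_dropout(matrix, params.p_d, rng)
    return mutated, matrix
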