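"""Rooted lineage trees with branch lengths.

A :class:`LineageTree` wraps a :class:`networkx.DiGraph` whose edges carry a
``length`` attribute (in normalized tree-height units, so an ultrametric
ground-truth tree has every leaf at depth 1).  Simulated trees additionally
carry a per-node integer ``states`` vector recording the CRISPR-Cas9
character states of that cell.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass

import dendropy
import networkx as nx
import numpy as np

__all__ = ["LineageTree", "TripletGeometry"]


@dataclass(frozen=True)
class TripletGeometry:
    """Geometry of a resolved leaf triplet (a, b | outgroup).

    ``d`` is the depth of the triplet's LCA and ``alpha`` the separation
    dist(LCA(a,b,c), LCA(a,b)) between the triplet ancestor and the ingroup
    ancestor.  Both are in tree-height units, so 0 <= d <= 1 and
    0 <= alpha <= 1 - d.
    """

    outgroup: str
    d: float
    alpha: float

    def __post_init__(self):
        if not (-1e-9 <= self.d <= 1 + 1e-9):
            raise ValueError(f"triplet LCA depth d={self.d} outside [0, 1]")
        if not (-1e-9 <= self.alpha <= 1 - self.d + 1e-9):
            raise ValueError(
                f"separation alpha={self.alpha} outside [0, 1 - d] (d={self.d})"
            )


class LineageTree:
    """Rooted tree with branch lengths and optional node character states."""

    def __init__(self, graph: nx.DiGraph, root=None):
        if graph.number_of_nodes() == 0:
            raise ValueError("empty tree")
        roots = [v for v in graph.nodes if graph.in_degree(v) == 0]
        if root is None:
            if len(roots) != 1:
                raise ValueError(f"expected exactly one root, found {roots}")
            root = roots[0]
        elif graph.in_degree(root) != 0:
            raise ValueError(f"declared root {root!r} has a parent")
        if not nx.is_tree(graph.to_undirected(as_view=True)):
            raise ValueError("graph is not a tree")
        self.graph = graph
        self.root = root
        self._depths = None
        self._leaves = None

    # ------------------------------------------------------------------ basic
    @property
    def leaves(self) -> list:
        if self._leaves is None:
            self._leaves = sorted(
                v for v in self.graph.nodes if self.graph.out_degree(v) == 0
            )
        return self._leaves

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def children(self, v):
        return list(self.graph.successors(v))

    def parent(self, v):
        preds = list(self.graph.predecessors(v))
        return preds[0] if preds else None

    def edge_length(self, u, v) -> float:
        return float(self.graph.edges[u, v].get("length", 1.0))

    def edge_lengths(self) -> np.ndarray:
        return np.array([self.edge_length(u, v) for u, v in self.graph.edges])

    # ------------------------------------------------------------ depth / LCA
    def depth(self, v) -> float:
        """Branch-length distance from the root."""
        return self.depths[v]

    @property
    def depths(self) -> dict:
        if self._depths is None:
            d = {self.root: 0.0}
            for u, v in nx.dfs_edges(self.graph, self.root):
                d[v] = d[u] + self.edge_length(u, v)
            self._depths = d
        return self._depths

    def dist(self, u, v) -> float:
        w = self.lca(u, v)
        return self.depth(u) + self.depth(v) - 2 * self.depth(w)

    def ancestors_path(self, v) -> list:
        """Path from the root down to ``v`` (inclusive)."""
        path = [v]
        while (p := self.parent(path[-1])) is not None:
            path.append(p)
        return path[::-1]

    def lca(self, *nodes):
        if not nodes:
            raise ValueError("lca of empty node set")
        common = None
        for v in nodes:
            anc = set(self.ancestors_path(v))
            common = anc if common is None else common & anc
        return max(common, key=lambda u: self.depths[u])

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        return all(abs(self.depth(v) - 1.0) <= tol for v in self.leaves)

    # --------------------------------------------------------------- triplets
    def lca_depth_matrices(self, leaves=None):
        """Pairwise leaf LCA depths, O(n^2) by postorder accumulation.

        Returns ``(D_len, D_cnt, index)`` where ``D_len[i, j]`` is the
        branch-length depth of LCA(leaf_i, leaf_j), ``D_cnt`` the edge-count
        depth, and ``index`` maps leaf label -> row.
        """
        if leaves is None:
            leaves = self.leaves
        index = {name: i for i, name in enumerate(leaves)}
        n = len(leaves)
        D_len = np.zeros((n, n))
        D_cnt = np.zeros((n, n), dtype=np.int64)
        cnt_depth = {self.root: 0}
        for u, v in nx.dfs_edges(self.graph, self.root):
            cnt_depth[v] = cnt_depth[u] + 1
        leafsets: dict = {}
        for v in nx.dfs_postorder_nodes(self.graph, self.root):
            kids = self.children(v)
            if not kids:
                arr = np.array([index[v]]) if v in index else np.array([], dtype=int)
                leafsets[v] = arr
                if v in index:
                    i = index[v]
                    D_len[i, i] = self.depth(v)
                    D_cnt[i, i] = cnt_depth[v]
                continue
            sets = [leafsets.pop(c) for c in kids]
            for a, b in itertools.combinations(sets, 2):
                if len(a) and len(b):
                    D_len[np.ix_(a, b)] = self.depth(v)
                    D_len[np.ix_(b, a)] = self.depth(v)
                    D_cnt[np.ix_(a, b)] = cnt_depth[v]
                    D_cnt[np.ix_(b, a)] = cnt_depth[v]
            leafsets[v] = np.concatenate(sets) if sets else np.array([], dtype=int)
        return D_len, D_cnt, index

    def triplet_geometry(self, a, b, c) -> TripletGeometry | None:
        """Resolve the triplet {a, b, c}; ``None`` if it is a true polytomy."""
        w = self.lca(a, b, c)
        d = self.depth(w)
        pairs = {c: (a, b), b: (a, c), a: (b, c)}
        best, best_depth = None, d
        for out, (x, y) in pairs.items():
            dep = self.depth(self.lca(x, y))
            if dep > best_depth + 1e-12:
                best, best_depth = out, dep
        if best is None:
            return None
        return TripletGeometry(outgroup=best, d=d, alpha=best_depth - d)

    # ------------------------------------------------------------------ states
    def states(self, v) -> np.ndarray:
        return self.graph.nodes[v]["states"]

    def has_states(self) -> bool:
        return all("states" in self.graph.nodes[v] for v in self.leaves)

    # ----------------------------------------------------------------- newick
    def to_newick(self) -> str:
        """Serialize to a Newick string with branch lengths."""
        tree = _to_dendropy(self)
        return tree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, newick: str) -> "LineageTree":
        dt = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
        return _from_dendropy(dt)

    def copy(self) -> "LineageTree":
        return LineageTree(self.graph.copy(), self.root)

    def __repr__(self):
        return f"LineageTree(n_leaves={self.n_leaves}, root={self.root!r})"


def _to_dendropy(tree: LineageTree) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dt = dendropy.Tree(taxon_namespace=taxa)
    nodes = {tree.root: dt.seed_node}
    for u, v in nx.dfs_edges(tree.graph, tree.root):
        child = dendropy.Node()
        child.edge.length = tree.edge_length(u, v)
        nodes[u].add_child(child)
        nodes[v] = child
    for v, dn in nodes.items():
        if tree.graph.out_degree(v) == 0:
            dn.taxon = taxa.new_taxon(str(v))
        else:
            dn.label = str(v)
    return dt


def _from_dendropy(dt: dendropy.Tree) -> LineageTree:
    g = nx.DiGraph()
    counter = itertools.count()
    names: dict = {}

    def name_of(node):
        if node in names:
            return names[node]
        if node.taxon is not None:
            nm = node.taxon.label
        elif node.label:
            nm = node.label
        else:
            nm = f"i{next(counter)}"
        names[node] = nm
        return nm

    root = name_of(dt.seed_node)
    g.add_node(root)
    for node in dt.preorder_node_iter():
        for child in node.child_nodes():
            length = child.edge.length if child.edge.length is not None else 1.0
            g.add_edge(name_of(node), name_of(child), length=float(length))
    return LineageTree(g, root)
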