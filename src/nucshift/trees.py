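"""Rooted phylogenetic trees, regime paintings, and clade utilities.

A :class:`RootedTree` is a light array-backed container indexed so that node
``i`` is the ``i``-th node in postorder (the root is always the last index).
This fixed indexing is what the pruning likelihood engine iterates over, and
it gives every analysis a stable, canonical handle on nodes: across runs and
across trees with the same topology a node is identified by the set of leaf
labels below it (:meth:`RootedTree.leafset`).

Newick parsing and serialization are delegated to dendropy; trees may carry
internal-node labels (e.g. support values) and NHX-style comments, which are
preserved on round trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "RootedTree",
    "RegimePainting",
    "NewickError",
    "UnrootedTreeError",
    "read_newick",
    "read_newick_list",
    "write_newick",
    "eligible_nodes",
    "paint_regimes",
]


class NewickError(ValueError):
    """Malformed Newick input."""


class UnrootedTreeError(NewickError):
    """Tree is unrooted (basal polytomy) where a rooted tree is required."""


class RootedTree:
    """Rooted tree with branch lengths, indexed in postorder.

    Attributes
    ----------
    n_nodes, n_leaves : int
    parent : ndarray of int
        ``parent[i]`` is the parent index of node ``i`` (-1 for the root).
    children : list of list of int
        Child indices per node (empty for leaves).
    branch_length : ndarray of float
        Length of the edge subtending each node; ``nan`` for the root.
    labels : list of str or None
        Taxon names for leaves; optional labels (e.g. support) for internals.
    """

    def __init__(self, parent, children, branch_length, labels, comments=None):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = [list(c) for c in children]
        self.branch_length = np.asarray(branch_length, dtype=float)
        self.labels = list(labels)
        self.comments = list(comments) if comments is not None else [None] * len(labels)
        self.n_nodes = len(self.labels)
        self.root = int(np.flatnonzero(self.parent < 0)[0])
        self._validate()
        self._leafsets = None
        self._by_leafset = None

    # -- construction -----------------------------------------------------

    @classmethod
    def _from_dendropy(cls, dtree: dendropy.Tree) -> "RootedTree":
        nodes = list(dtree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        blen = np.full(n, np.nan)
        labels: list[str | None] = [None] * n
        comments: list[str | None] = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                children[parent[i]].append(i)
                blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                labels[i] = nd.taxon.label if nd.taxon is not None else nd.label
            else:
                labels[i] = nd.label
            if nd.comments:
                comments[i] = ";".join(str(c) for c in nd.comments)
        return cls(parent, children, blen, labels, comments)

    def _validate(self):
        if (self.branch_length[self.is_leaf_mask() | ~self.is_leaf_mask()] < -1e-12).any():
            raise ValueError("negative branch length")
        leaves = [self.labels[i] for i in self.leaf_indices()]
        if any(l is None for l in leaves):
            raise NewickError("unnamed leaf")
        if len(set(leaves)) != len(leaves):
            raise NewickError("duplicate leaf labels")

    # -- basic structure ---------------------------------------------------

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def is_leaf_mask(self) -> np.ndarray:
        return np.array([not c for c in self.children], dtype=bool)

    def leaf_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    @property
    def n_leaves(self) -> int:
        return int(self.is_leaf_mask().sum())

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_indices()]

    def postorder(self) -> range:
        return range(self.n_nodes)

    def preorder(self) -> range:
        # reverse postorder visits every parent before its children
        return range(self.n_nodes - 1, -1, -1)

    def internal_indices(self, include_root: bool = True) -> list[int]:
        out = [i for i in range(self.n_nodes) if not self.is_leaf(i)]
        if not include_root:
            out = [i for i in out if i != self.root]
        return out

    def clade_sizes(self) -> np.ndarray:
        """Number of leaves below (and including) each node."""
        sizes = np.zeros(self.n_nodes, dtype=np.int64)
        for i in self.postorder():
            sizes[i] = 1 if self.is_leaf(i) else sum(sizes[c] for c in self.children[i])
        return sizes

    def depths_edges(self) -> np.ndarray:
        """Number of edges from the root to each node."""
        d = np.zeros(self.n_nodes, dtype=np.int64)
        for i in self.preorder():
            if i != self.root:
                d[i] = d[self.parent[i]] + 1
        return d

    def node_depths(self) -> np.ndarray:
        """Sum of branch lengths from the root to each node."""
        d = np.zeros(self.n_nodes)
        for i in self.preorder():
            if i != self.root:
                d[i] = d[self.parent[i]] + self.branch_length[i]
        return d

    def ancestors(self, i: int) -> list[int]:
        out = []
        while self.parent[i] >= 0:
            i = int(self.parent[i])
            out.append(i)
        return out

    def descendants(self, i: int) -> list[int]:
        """All strict descendants of node ``i`` (postorder)."""
        out = []
        stack = list(self.children[i])
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return out

    def path_distance(self, u: int, v: int) -> int:
        """Number of edges on the path between two nodes."""
        depth = self.depths_edges()
        du, dv = int(depth[u]), int(depth[v])
        dist = 0
        while du > dv:
            u = int(self.parent[u]); du -= 1; dist += 1
        while dv > du:
            v = int(self.parent[v]); dv -= 1; dist += 1
        while u != v:
            u = int(self.parent[u]); v = int(self.parent[v]); dist += 2
        return dist

    # -- canonical identity ------------------------------------------------

    def leafset(self, i: int) -> frozenset:
        """Canonical identity of a node: the leaf labels of its clade."""
        if self._leafsets is None:
            sets = [None] * self.n_nodes
            for j in self.postorder():
                if self.is_leaf(j):
                    sets[j] = frozenset([self.labels[j]])
                else:
                    s = frozenset()
                    for c in self.children[j]:
                        s |= sets[c]
                    sets[j] = s
            self._leafsets = sets
        return self._leafsets[i]

    def node_by_leafset(self, s) -> int:
        if self._by_leafset is None:
            self._by_leafset = {self.leafset(i): i for i in range(self.n_nodes)}
        return self._by_leafset[frozenset(s)]

    def clades(self, nontrivial: bool = True) -> set:
        """Set of leaf-label clades (internal nodes, root excluded)."""
        out = set()
        for i in self.internal_indices(include_root=False):
            out.add(self.leafset(i))
        if not nontrivial:
            out |= {self.leafset(i) for i in self.leaf_indices()}
        return out

    # -- I/O ----------------------------------------------------------------

    def _to_dendropy(self, precision: int = 12) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dnodes = [None] * self.n_nodes
        for i in self.postorder():
            nd = dendropy.Node()
            if self.is_leaf(i):
                nd.taxon = taxa.require_taxon(label=self.labels[i])
            elif self.labels[i]:
                nd.label = self.labels[i]
            if self.comments[i]:
                nd.comments.append(self.comments[i])
            if not np.isnan(self.branch_length[i]):
                nd.edge.length = float(self.branch_length[i])
            for c in self.children[i]:
                nd.add_child(dnodes[c])
            dnodes[i] = nd
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node = dnodes[self.root]
        tree.is_rooted = True
        return tree

    def to_newick(self, precision: int = 12) -> str:
        t = self._to_dendropy()
        s = t.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_item_comments=False,
            unquoted_underscores=True,
            preserve_spaces=True,
            real_value_format_specifier=f".{precision}g",
        )
        return s.strip()

    def __repr__(self):
        return f"<RootedTree {self.n_leaves} leaves, {self.n_nodes} nodes>"


def read_newick(text: str, rooted: bool = True) -> RootedTree:
    """Parse a Newick string into a :class:`RootedTree`.

    Parameters
    ----------
    text : str
        A single Newick tree description.
    rooted : bool
        When True (default) a basal polytomy is rejected with
        :class:`UnrootedTreeError` — shift searches require a rooted
        bifurcating phylogram.  Set False for collapsed gene trees.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"Newick parse error: {exc}") from exc
    nch = len(dtree.seed_node.child_nodes())
    if nch == 0:
        raise NewickError("empty tree")
    if rooted and nch > 2:
        raise UnrootedTreeError(
            f"tree root has {nch} children; a rooted (bifurcating at the root) "
            "tree is required"
        )
    return RootedTree._from_dendropy(dtree)


def read_newick_list(text: str, rooted: bool = False) -> list[RootedTree]:
    """Parse a multi-tree Newick document (e.g. a gene-tree file)."""
    trees = dendropy.TreeList.get(
        data=text, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    return [read_newick(t.as_string(schema="newick").strip(), rooted=rooted) for t in trees]


def write_newick(tree: RootedTree, precision: int = 12) -> str:
    return tree.to_newick(precision=precision)


def eligible_nodes(tree: RootedTree, m: int = 4) -> list[int]:
    """Non-root internal nodes whose clade holds at least ``m`` leaves.

    These are the candidate shift positions of the search; returned in
    postorder (tips toward root).  ``m`` is the minimum clade size.
    """
    if m < 2:
        raise ValueError("minimum clade size m must be >= 2")
    sizes = tree.clade_sizes()
    return [
        i for i in tree.postorder()
        if not tree.is_leaf(i) and i != tree.root and sizes[i] >= m
    ]


@dataclass(frozen=True)
class RegimePainting:
    """Assignment of every node (edge) to a compositional regime.

    Regime 0 is the ancestral (root) regime.  Under the stem-edge convention
    (the default throughout) the branch subtending a shift node already
    belongs to the shifted regime, so ``regime[i]`` is simultaneously the
    regime of node ``i`` and of the edge into it.
    """

    tree: RootedTree
    shift_nodes: tuple
    regime: np.ndarray
    stem_edge: bool = True

    @property
    def n_regimes(self) -> int:
        return len(self.shift_nodes) + 1

    def regime_of(self, node: int) -> int:
        return int(self.regime[node])

    def edge_regime(self, node: int) -> int:
        """Regime governing the branch subtending ``node``."""
        if not self.stem_edge and node in self.shift_nodes:
            return int(self.regime[self.tree.parent[node]])
        return int(self.regime[node])

    def edge_regimes(self) -> np.ndarray:
        """Regime per edge (indexed by child node), honoring the convention."""
        r = self.regime.copy()
        if not self.stem_edge:
            for s in self.shift_nodes:
                r[s] = self.regime[self.tree.parent[s]]
        return r


def paint_regimes(
    tree: RootedTree, shift_nodes, stem_edge: bool = True
) -> RegimePainting:
    """Paint regimes on a tree given an ordered collection of shift nodes.

    Each node receives the regime of its nearest ancestor-or-self shift
    node (nested shifts override outer ones); nodes with no shift ancestor
    stay in regime 0.  Shift ``shift_nodes[k]`` founds regime ``k + 1``.
    """
    shift_nodes = [int(s) for s in shift_nodes]
    if len(set(shift_nodes)) != len(shift_nodes):
        raise ValueError("duplicate shift nodes")
    for s in shift_nodes:
        if s == tree.root:
            raise ValueError("shift on the root is not allowed (root is regime 0)")
        if tree.is_leaf(s):
            raise ValueError(f"shift node {s} is a leaf")
    regime_id = {s: k + 1 for k, s in enumerate(shift_nodes)}
    regime = np.zeros(tree.n_nodes, dtype=np.int64)
    for i in tree.preorder():
        if i in regime_id:
            regime[i] = regime_id[i]
        elif i != tree.root:
            regime[i] = regime[tree.parent[i]]
    return RegimePainting(tree, tuple(shift_nodes), regime, stem_edge)
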