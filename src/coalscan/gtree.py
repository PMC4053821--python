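"""Lightweight gene-tree container.

Trees are stored as parent arrays with leaves first, which makes the
bitmask operations behind Robinson-Foulds distances, clade frequency
tables, consensus construction and STAR rank distances cheap.  Newick
input goes through dendropy; simulated trees come straight from the
coalescent kernel as (parent, node-age) arrays.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

__all__ = ["GeneTree", "TreeSet", "tree_from_clades", "root_at"]

Window = tuple[str, int, int]


@dataclass
class GeneTree:
    """A rooted tree over labelled leaves.

    ``parent[i]`` is the parent node of node ``i`` (-1 for the root);
    leaves occupy indices ``0..n_leaves-1`` and ``labels[i]`` names leaf
    ``i``.  ``blen[i]`` is the length of the branch above node ``i``
    (generations for simulated trees, substitutions/site for inferred
    ones; 0 at the root).  Internal node order is unconstrained except
    that a parent always has a larger index than its children.
    """

    labels: tuple[str, ...]
    parent: np.ndarray
    blen: np.ndarray
    support: Optional[np.ndarray] = None
    window: Optional[Window] = None

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int32)
        self.blen = np.asarray(self.blen, dtype=np.float64)
        if np.any(self.blen[:-1] < -1e-12):
            raise ValueError("negative branch length")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_times(
        cls,
        labels: Sequence[str],
        parent: np.ndarray,
        times: np.ndarray,
        window: Optional[Window] = None,
    ) -> "GeneTree":
        """Build from node ages (coalescent output): blen = age(parent) - age."""
        parent = np.asarray(parent, dtype=np.int32)
        times = np.asarray(times, dtype=np.float64)
        blen = np.zeros(len(parent))
        nz = parent >= 0
        blen[nz] = times[parent[nz]] - times[nz]
        return cls(tuple(labels), parent, blen, window=window)

    @classmethod
    def from_newick(cls, newick: str, window: Optional[Window] = None) -> "GeneTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dtree, window=window)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree", window: Optional[Window] = None) -> "GeneTree":
        leaves = [nd for nd in dtree.leaf_node_iter()]
        labels = tuple(lf.taxon.label for lf in leaves)
        internals = [nd for nd in dtree.postorder_internal_node_iter()]
        index = {id(nd): i for i, nd in enumerate(leaves)}
        for k, nd in enumerate(internals):  # postorder: children precede parents
            index[id(nd)] = len(leaves) + k
        n = len(leaves) + len(internals)
        parent = np.full(n, -1, dtype=np.int32)
        blen = np.zeros(n)
        support = np.full(n, np.nan)
        has_support = False
        for nd in dtree.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if not nd.is_leaf() and nd.label is not None:
                try:
                    support[i] = float(nd.label)
                    has_support = True
                except ValueError:
                    pass
        return cls(labels, parent, np.maximum(blen, 0.0),
                   support=support if has_support else None, window=window)

    # -- views -------------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                out[p].append(i)
        return out

    def leaf_masks(self, universe: Sequence[str]) -> np.ndarray:
        """Per-node bitmask of descendant leaves, bits indexed by
        ``universe`` order.  Requires every leaf label in ``universe``."""
        idx = {lab: k for k, lab in enumerate(universe)}
        if len(universe) > 63:
            raise ValueError("bitmask representation limited to 63 taxa")
        mask = np.zeros(self.n_nodes, dtype=np.int64)
        for i, lab in enumerate(self.labels):
            mask[i] = np.int64(1) << idx[lab]
        # parents always carry a larger index than their children
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                if p <= i:
                    raise ValueError("parent index must exceed child index")
                mask[p] |= mask[i]
        return mask

    def clades(self, universe: Sequence[str]) -> set[int]:
        """Rooted clades (including leaves' singletons and the full set)
        as bitmasks over ``universe``."""
        return set(int(m) for m in self.leaf_masks(universe))

    def bipartitions(self, universe: Sequence[str]) -> set[int]:
        """Non-trivial unrooted bipartitions as bitmasks over ``universe``,
        each normalized to the side *not* containing ``universe[0]``."""
        full = (np.int64(1) << len(universe)) - np.int64(1)
        ref = np.int64(1)
        masks = self.leaf_masks(universe)
        out: set[int] = set()
        for i in range(self.n_nodes):
            m = masks[i]
            if m & ref:
                m = full & ~m
            c = int(m).bit_count()
            if 2 <= c <= len(self.labels) - 2:
                out.add(int(m))
        return out

    # -- output ------------------------------------------------------------
    def to_newick(self, *, lengths: bool = True, supports: bool = True,
                  fmt: str = "%.8g") -> str:
        ch = self.children()

        def rec(i: int) -> str:
            if i < self.n_leaves:
                s = _quote(self.labels[i])
            else:
                s = "(" + ",".join(rec(c) for c in ch[i]) + ")"
                if supports and self.support is not None and np.isfinite(self.support[i]):
                    s += fmt % self.support[i]
            if lengths and self.parent[i] >= 0:
                s += ":" + fmt % self.blen[i]
            return s

        return rec(self.root) + ";"


def _quote(label: str) -> str:
    if re.search(r"[\s()\[\]{}:;,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


class TreeSet:
    """An ordered gene-tree collection over a shared taxon universe."""

    def __init__(self, trees: Sequence[GeneTree], taxa: Optional[Sequence[str]] = None):
        self.trees = list(trees)
        if taxa is None:
            seen: dict[str, None] = {}
            for t in self.trees:
                for lab in t.labels:
                    seen.setdefault(lab)
            taxa = list(seen)
        self.taxa = tuple(taxa)
        for t in self.trees:
            missing = set(t.labels) - set(self.taxa)
            if missing:
                raise ValueError(f"tree leaves {missing} outside taxon universe")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i) -> GeneTree:
        return self.trees[i]

    def to_newick_file(self, path) -> None:
        """One tree per line, preceded by a ``#window=chrom:start-end``
        comment when the tree carries window provenance."""
        with open(path, "w") as fh:
            for t in self.trees:
                if t.window is not None:
                    c, s, e = t.window
                    fh.write(f"#window={c}:{s}-{e}\n")
                fh.write(t.to_newick() + "\n")

    @classmethod
    def from_newick_file(cls, path, taxa: Optional[Sequence[str]] = None) -> "TreeSet":
        trees = []
        window = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    m = re.match(r"#window=([^:]+):(\d+)-(\d+)", line)
                    window = (m.group(1), int(m.group(2)), int(m.group(3))) if m else None
                    continue
                trees.append(GeneTree.from_newick(line, window=window))
                window = None
        return cls(trees, taxa=taxa)


def tree_from_clades(
    clade_support: dict[int, float],
    universe: Sequence[str],
) -> GeneTree:
    """Assemble a rooted tree from a nesting-compatible set of clade
    bitmasks over ``universe``; ``clade_support`` values become node
    supports.  Leaves and the root clade are added implicitly."""
    n = len(universe)
    full = (1 << n) - 1
    clades = {m for m in clade_support if m.bit_count() > 1 and m != full}
    # sort by size ascending so children are created before parents
    ordered = sorted(clades, key=lambda m: (m.bit_count(), m))
    nodes = [1 << i for i in range(n)] + ordered + [full]
    parent = np.full(len(nodes), -1, dtype=np.int32)
    for i, m in enumerate(nodes[:-1]):
        # parent = smallest strictly-containing clade
        best = len(nodes) - 1
        for j in range(n, len(nodes) - 1):
            mj = nodes[j]
            if mj != m and (m & mj) == m:
                if nodes[best] == full or mj.bit_count() < nodes[best].bit_count():
                    best = j
        parent[i] = best
    support = np.full(len(nodes), np.nan)
    for j in range(n, len(nodes)):
        m = nodes[j]
        if m in clade_support:
            support[j] = clade_support[m]
        elif m == full:
            support[j] = clade_support.get(full, 1.0)
    return GeneTree(tuple(universe), parent, np.ones(len(nodes)), support=support)


def root_at(tree: GeneTree, outgroup: str) -> GeneTree:
    """Reroot so that ``outgroup`` is a direct child of the root.

    The new root is placed on the branch above the outgroup leaf; a
    degree-two old root is suppressed.  Branch lengths are preserved
    (the split edge keeps its full length on the outgroup side's
    complement, which is immaterial to rank-based uses)."""
    if outgroup not in tree.labels:
        raise ValueError(f"outgroup {outgroup!r} not among tree leaves")
    o = tree.labels.index(outgroup)
    r = tree.root
    if tree.parent[o] == r:
        return tree
    # undirected adjacency with edge lengths
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(tree.n_nodes)}
    for i, p in enumerate(tree.parent):
        if p >= 0:
            adj[i].append((int(p), float(tree.blen[i])))
            adj[p].append((i, float(tree.blen[i])))
    # suppress a degree-2 old root
    if len(adj[r]) == 2:
        (a, la), (b, lb) = adj[r]
        adj[a] = [(x, l) for x, l in adj[a] if x != r] + [(b, la + lb)]
        adj[b] = [(x, l) for x, l in adj[b] if x != r] + [(a, la + lb)]
        del adj[r]
    # new root on the edge above the outgroup leaf
    (po, lo), = adj[o]
    new_root = max(adj) + 1
    adj[o] = [(new_root, lo / 2)]
    adj[po] = [(x, l) for x, l in adj[po] if x != o] + [(new_root, lo / 2)]
    adj[new_root] = [(o, lo / 2), (po, lo / 2)]
    # orient away from new root; relabel nodes leaves-first, parents after children
    old_leaves = [i for i in adj if i < tree.n_leaves]
    order: list[int] = []
    stack = [new_root]
    par: dict[int, tuple[int, float]] = {new_root: (-1, 0.0)}
    while stack:
        u = stack.pop()
        order.append(u)
        for v, l in adj[u]:
            if v not in par:
                par[v] = (u, l)
                stack.append(v)
    internals_new = [u for u in reversed(order) if u not in old_leaves]
    newid = {u: u for u in old_leaves}
    for k, u in enumerate(internals_new):
        newid[u] = tree.n_leaves + k
    n_new = len(newid)
    parent = np.full(n_new, -1, dtype=np.int32)
    blen = np.zeros(n_new)
    for u, (p, l) in par.items():
        if p >= 0:
            parent[newid[u]] = newid[p]
            blen[newid[u]] = l
    return GeneTree(tree.labels, parent, blen, window=tree.window)
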